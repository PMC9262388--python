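"""Probe QC against an equimolar pilot, strain-frequency estimation, and
standard-curve evaluation.

Each probe's frequency is the alternative-read fraction
``n_alt / (n_alt + n_ref)`` ("other" reads excluded from the denominator).
Against an equimolar pilot of ``S`` strains a probe must (1) report a
frequency within 3.5-fold of the expected ``1/S`` (closed band: the boundary
passes), (2) accumulate fewer than 20,000 "other" reads, and (3) have an
alt+ref total between 20,000 and 2,000,000 reads. The count thresholds are
tied to the original sequencing depth (~600k reads per probe); ``scaled``
rescales them proportionally for shallower runs. Probes may be marked exempt
(the reference strain's probes were retained despite failing QC, since a
strain derived from the reference genome has almost no unique SNVs to choose
from); exempt probes bypass the filter but stay flagged in provenance output.

Strain frequency per sample is the unweighted mean of its passing probes'
frequencies; strains with no usable probe are omitted and reported as
dropouts rather than imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .readquant import AlleleCountRecord

#: Average mapped reads per probe in the original equimolar pilot
#: (246,986,236 reads over 412 probes); reference point for depth rescaling.
REFERENCE_PILOT_DEPTH = 246_986_236 / 412


@dataclass(frozen=True)
class QcThresholds:
    """Probe QC criteria for an equimolar pilot of ``n_strains`` strains."""

    n_strains: int
    fold_band: float = 3.5
    other_max: float = 20_000
    total_min: float = 20_000
    total_max: float = 2_000_000

    def __post_init__(self):
        if self.fold_band <= 1:
            raise ValueError("fold_band must exceed 1")
        if not self.total_min < self.total_max:
            raise ValueError("total_min must be below total_max")
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")

    @property
    def expected_frequency(self) -> float:
        return 1.0 / self.n_strains

    def scaled(self, depth_scale: float) -> "QcThresholds":
        """Rescale the absolute count thresholds for a different depth.

        ``depth_scale`` is the ratio of the run's per-probe depth to the
        reference pilot depth (:data:`REFERENCE_PILOT_DEPTH`).
        """
        if depth_scale <= 0:
            raise ValueError("depth_scale must be positive")
        return replace(self, other_max=self.other_max * depth_scale,
                       total_min=self.total_min * depth_scale,
                       total_max=self.total_max * depth_scale)


@dataclass
class QcResult:
    probe_id: str
    observed_freq: float | None
    fail_reasons: frozenset[str]
    exempt: bool = False

    @property
    def passed(self) -> bool:
        return not self.fail_reasons

    @property
    def usable(self) -> bool:
        return self.passed or self.exempt


def mip_frequency(record: AlleleCountRecord) -> float | None:
    """Alternative-read fraction ``n_alt / (n_alt + n_ref)``.

    Returns ``None`` (with a warning) when the probe collected no ref or alt
    reads, so callers can skip the record.
    """
    denom = record.n_alt + record.n_ref
    if denom == 0:
        warnings.warn(f"probe {record.probe_id} sample {record.sample_id}: "
                      "no ref/alt reads, frequency undefined")
        return None
    return record.n_alt / denom


def qc_probe(record: AlleleCountRecord, thr: QcThresholds, *,
             exempt: bool = False) -> QcResult:
    """Evaluate one pilot record against all three criteria.

    Every violated criterion is reported, not just the first:
    ``band`` (frequency outside [expected/fold, expected*fold], inclusive),
    ``other`` (other-allele reads at or above ``other_max``), and
    ``total`` (alt+ref total outside [total_min, total_max]).
    """
    reasons = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        freq = mip_frequency(record)
    # closed band, compared cross-multiplied so "exactly 3.5-fold" passes
    # without float-division rounding:  1/(S*fold) <= alt/denom <= fold/S
    denom = record.n_alt + record.n_ref
    S, fold = thr.n_strains, thr.fold_band
    in_band = (freq is not None
               and record.n_alt * S * fold >= denom
               and record.n_alt * S <= fold * denom)
    if not in_band:
        reasons.add("band")
    if record.n_other_a + record.n_other_b >= thr.other_max:
        reasons.add("other")
    total = record.n_alt + record.n_ref
    if not (thr.total_min <= total <= thr.total_max):
        reasons.add("total")
    return QcResult(probe_id=record.probe_id, observed_freq=freq,
                    fail_reasons=frozenset(reasons), exempt=exempt)


def qc_panel(pilot_records: Sequence[AlleleCountRecord], thr: QcThresholds, *,
             exempt_strains: Iterable[str] = (),
             probe_strain: Mapping[str, str] | None = None) -> dict[str, QcResult]:
    """QC every pilot record; ``exempt_strains`` bypass filtering but stay flagged."""
    exempt_strains = set(exempt_strains)
    out = {}
    for rec in pilot_records:
        strain = probe_strain.get(rec.probe_id) if probe_strain else None
        out[rec.probe_id] = qc_probe(rec, thr, exempt=strain in exempt_strains)
    return out


def strain_frequencies(counts: Sequence[AlleleCountRecord],
                       qc: Mapping[str, QcResult] | None,
                       probe_strain: Mapping[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average passing probes' frequencies into per-sample strain frequencies.

    ``probe_strain`` maps probe_id to the strain whose unique SNV it carries
    (derivable from a :class:`~mipmeter.panel.PanelSpec` or a panel TSV).
    ``qc`` of ``None`` uses every probe. Returns ``(frequencies, dropouts)``
    long-format frames; dropouts lists (sample, strain) pairs with no usable
    probe.
    """
    if not counts:
        raise ValueError("no count records supplied")
    rows, dropped = [], []
    by_sample: dict[str, list[AlleleCountRecord]] = {}
    for rec in counts:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    all_strains = sorted(set(probe_strain.values()))
    for sample_id, recs in by_sample.items():
        per_strain: dict[str, list[float]] = {s: [] for s in all_strains}
        for rec in recs:
            strain = probe_strain.get(rec.probe_id)
            if strain is None:
                continue
            if qc is not None:
                res = qc.get(rec.probe_id)
                if res is None or not res.usable:
                    continue
            freq = mip_frequency(rec)
            if freq is None:
                continue
            per_strain[strain].append(freq)
        for strain in all_strains:
            freqs = per_strain[strain]
            if not freqs:
                dropped.append({"sample_id": sample_id, "strain_id": strain})
                continue
            rows.append({"sample_id": sample_id, "strain_id": strain,
                         "frequency": float(np.mean(freqs)),
                         "n_probes_used": len(freqs)})
    freq_df = pd.DataFrame(rows, columns=["sample_id", "strain_id", "frequency",
                                          "n_probes_used"])
    dropout_df = pd.DataFrame(dropped, columns=["sample_id", "strain_id"])
    return freq_df, dropout_df


@dataclass
class CurveFit:
    """Least-squares line of log10(observed) on log10(expected)."""

    r_squared: float
    slope: float
    intercept: float
    residuals: pd.DataFrame = field(repr=False, default=None)


def standard_curve_eval(observed: pd.DataFrame, expected: pd.DataFrame) -> CurveFit:
    """Regress log10 observed strain frequency on log10 known proportion.

    ``observed`` needs columns (strain_id, frequency); ``expected`` columns
    (strain_id, known_proportion), all proportions strictly positive. Zero
    observed frequencies are floored at half the smallest nonzero observed
    value before logging (with a warning), since the curve is evaluated on a
    log-log scale spanning orders of magnitude.
    """
    merged = observed.merge(expected, on="strain_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 strains with expected proportions")
    if (merged["known_proportion"] <= 0).any():
        raise ValueError("expected proportions must be strictly positive")
    obs = merged["frequency"].to_numpy(dtype=float)
    if (obs == 0).any():
        nonzero = obs[obs > 0]
        if nonzero.size == 0:
            raise ValueError("all observed frequencies are zero")
        floor = nonzero.min() / 2
        warnings.warn(f"flooring {(obs == 0).sum()} zero observed frequencies at {floor:g}")
        obs = np.where(obs == 0, floor, obs)
    x = np.log10(merged["known_proportion"].to_numpy(dtype=float))
    y = np.log10(obs)
    fit = stats.linregress(x, y)
    resid = merged.assign(log10_expected=x, log10_observed=y,
                          residual=y - (fit.intercept + fit.slope * x))
    return CurveFit(r_squared=float(fit.rvalue ** 2), slope=float(fit.slope),
                    intercept=float(fit.intercept), residuals=resid)


# ---------------------------------------------------------------------------
# I/O helpers

def qc_to_frame(qc: Mapping[str, QcResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "probe_id": r.probe_id,
        "observed_freq": math.nan if r.observed_freq is None else r.observed_freq,
        "pass": r.passed, "exempt": r.exempt,
        "fail_reasons": ",".join(sorted(r.fail_reasons)),
    } for r in qc.values()])


def frame_to_qc(df: pd.DataFrame) -> dict[str, QcResult]:
    out = {}
    for row in df.itertuples(index=False):
        reasons = frozenset(str(row.fail_reasons).split(",")) - {"", "nan"}
        freq = None if pd.isna(row.observed_freq) else float(row.observed_freq)
        out[row.probe_id] = QcResult(probe_id=row.probe_id, observed_freq=freq,
                                     fail_reasons=reasons, exempt=bool(row.exempt))
    return out
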