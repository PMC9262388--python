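"""Synthetic pooled-competition experiments with recorded ground truth.

The simulator emulates the selection-and-sequencing design: a pool of S
strains starts near equal composition (per-replicate baseline drawn from a
symmetric Dirichlet), starves through days {1, 9, 13, 17}, and each sampled
aliquot recovers and reproduces before sequencing. A strain's weight at day t
is

    baseline * [ survival(t; half_life_s) * exp(gain_s * survival(t)) ] ** gamma(t)

with the same declining logistic survival curve used by the validation
module, an optional per-strain recovery/fecundity multiplier that grows with
survival advantage, and an optional late-day attenuation exponent gamma(t)
(default 1) modelling the compression of strain differences when late
recovery cultures produce few progeny. Frequencies are the renormalized
weights.

Sequencing is modelled per probe: depth is Poisson around a mean, the
alternative-read probability is the strain frequency distorted by a per-probe
log-normal capture bias (unit mean), and a per-base substitution error
reallocates reads to the two "other" allele classes (ref<->alt cross-error is
neglected as second-order, so the expected alt fraction of assigned reads is
the true frequency times 1 minus the error leakage).
All randomness flows from a single seed; counts mode and FASTQ mode realize
the same drawn counts, so piping simulated FASTQ through the read counter
reproduces the count tables exactly.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .panel import ARM_LENGTH, CAPTURE_SIZE, UMI_LENGTH, MipProbe, PanelSpec, UniqueSnv
from .readquant import ReadLayout, other_alleles

DEFAULT_TIMEPOINTS = (1, 9, 13, 17)

#: Seven-strain mixing ladder spanning three orders of magnitude (renormalized).
STANDARD_CURVE_LADDER = tuple(np.logspace(-3, 0, 7) / np.logspace(-3, 0, 7).sum())


@dataclass
class SimConfig:
    """All knobs of one simulated experiment; every value has a default that
    mirrors the pooled starvation design (5 replicates, days 1/9/13/17, four
    probes per strain, ~10^4 reads per probe)."""

    n_strains: int
    strain_half_life: Sequence[float]
    replicates: int = 5
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS
    recovery_gain: Sequence[float] | None = None
    survival_rate: float = 0.35           # logistic steepness, per day
    baseline_concentration: float = 100.0  # Dirichlet concentration per strain
    probes_per_strain: int = 4
    probe_depth_mean: float = 10_000.0
    probe_bias_sd: float = 0.3            # log-scale spread of capture bias
    error_rate: float = 0.002             # per-base substitution probability
    late_attenuation: Mapping[int, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 2:
            raise ConfigError("n_strains must be >= 2")
        hl = np.asarray(self.strain_half_life, dtype=float)
        if hl.size != self.n_strains or np.any(hl <= 0):
            raise ConfigError("strain_half_life needs one positive value per strain")
        if self.recovery_gain is None:
            self.recovery_gain = np.zeros(self.n_strains)
        self.recovery_gain = np.asarray(self.recovery_gain, dtype=float)
        if self.recovery_gain.size != self.n_strains:
            raise ConfigError("recovery_gain needs one value per strain")
        if not (0 <= self.error_rate <= 0.1):
            raise ConfigError("error_rate must lie in [0, 0.1]")
        for name in ("replicates", "probes_per_strain"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.baseline_concentration <= 0 or self.probe_depth_mean <= 0:
            raise ConfigError("concentrations and depths must be positive")
        self.strain_half_life = hl
        self.timepoints = tuple(int(t) for t in self.timepoints)

    @classmethod
    def default(cls, n_strains: int = 30, replicates: int = 5, seed: int = 0,
                **kw) -> "SimConfig":
        """Graded-fitness default: half-lives spread evenly from 6 to 16 days."""
        return cls(n_strains=n_strains, replicates=replicates,
                   strain_half_life=np.linspace(6.0, 16.0, n_strains),
                   seed=seed, **kw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"simulator config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown simulator config keys: {sorted(bad)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strain_half_life"] = [float(x) for x in self.strain_half_life]
        d["recovery_gain"] = [float(x) for x in self.recovery_gain]
        d["timepoints"] = list(self.timepoints)
        return d


def default_strain_ids(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(n)]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    strain_ids: list[str]
    baseline: np.ndarray            # (replicates, strains)
    frequency: np.ndarray           # (replicates, strains, timepoints)
    probe_ids: list[str]
    probe_strain: dict[str, str]    # probe_id -> strain_id
    probe_bias: np.ndarray          # per probe, unit-mean log-normal
    config: SimConfig = field(repr=False, default=None)

    def frequency_frame(self) -> pd.DataFrame:
        rows = []
        cfg = self.config
        for r in range(cfg.replicates):
            for s, strain in enumerate(self.strain_ids):
                rows.append({"replicate": r, "strain_id": strain, "day": 0,
                             "frequency": float(self.baseline[r, s]),
                             "is_baseline": True})
                for k, t in enumerate(cfg.timepoints):
                    rows.append({"replicate": r, "strain_id": strain, "day": t,
                                 "frequency": float(self.frequency[r, s, k]),
                                 "is_baseline": False})
        return pd.DataFrame(rows)


def _survival(t: np.ndarray, half_life: np.ndarray, rate: float) -> np.ndarray:
    """Declining logistic survival, 0.5 at t = half_life (same form as
    :func:`mipmeter.validation.fit_survival`)."""
    return 1.0 / (1.0 + np.exp(rate * (t[:, None] - half_life[None, :])))


def simulate_trajectories(config: SimConfig,
                          strain_ids: Sequence[str] | None = None) -> SimTruth:
    """Draw baselines and deterministic selection trajectories; also draws the
    per-probe capture biases used by the read simulators."""
    rng = np.random.default_rng(config.seed)
    S, R = config.n_strains, config.replicates
    ids = list(strain_ids) if strain_ids is not None else default_strain_ids(S)
    if len(ids) != S:
        raise ConfigError("strain_ids length must equal n_strains")
    baseline = rng.dirichlet(np.full(S, config.baseline_concentration), size=R)

    t = np.asarray(config.timepoints, dtype=float)
    surv = _survival(t, config.strain_half_life, config.survival_rate)  # (T, S)
    mult = np.exp(config.recovery_gain[None, :] * surv)
    gamma = np.array([(config.late_attenuation or {}).get(int(day), 1.0) for day in t])
    selection = (surv * mult) ** gamma[:, None]  # (T, S)

    weights = baseline[:, None, :] * selection[None, :, :]       # (R, T, S)
    freq = weights / weights.sum(axis=2, keepdims=True)
    freq = np.transpose(freq, (0, 2, 1))                         # (R, S, T)

    n_probes = S * config.probes_per_strain
    sd = config.probe_bias_sd
    bias = rng.lognormal(mean=-sd ** 2 / 2, sigma=sd, size=n_probes) if sd > 0 \
        else np.ones(n_probes)
    probe_ids = [f"{ids[s]}_p{k}" for s in range(S) for k in range(config.probes_per_strain)]
    probe_strain = {f"{ids[s]}_p{k}": ids[s]
                    for s in range(S) for k in range(config.probes_per_strain)}
    return SimTruth(strain_ids=ids, baseline=baseline, frequency=freq,
                    probe_ids=probe_ids, probe_strain=probe_strain,
                    probe_bias=bias, config=config)


def _sample_probe_counts(rng, freq_by_strain: Mapping[str, float], truth: SimTruth,
                         sample_id: str, depth_mean: float, error_rate: float) -> list[dict]:
    rows = []
    for p, pid in enumerate(truth.probe_ids):
        f = freq_by_strain[truth.probe_strain[pid]]
        b = truth.probe_bias[p]
        p_alt = f * b / (f * b + (1.0 - f)) if f < 1.0 else 1.0
        depth = rng.poisson(depth_mean)
        n_alt0 = rng.binomial(depth, p_alt) if depth else 0
        n_ref0 = depth - n_alt0
        e = error_rate
        if e > 0:
            # substitution error sends reads to the two "other" alleles (e/2
            # each); ref<->alt cross-error is neglected, so the alt fraction
            # among ref+alt reads stays an unbiased frequency estimate
            ref_fate = rng.multinomial(n_ref0, [1 - e, 0.0, e / 2, e / 2])
            alt_fate = rng.multinomial(n_alt0, [0.0, 1 - e, e / 2, e / 2])
        else:
            ref_fate = np.array([n_ref0, 0, 0, 0])
            alt_fate = np.array([0, n_alt0, 0, 0])
        rows.append({"sample_id": sample_id, "probe_id": pid,
                     "n_ref": int(ref_fate[0] + alt_fate[0]),
                     "n_alt": int(ref_fate[1] + alt_fate[1]),
                     "n_other_a": int(ref_fate[2] + alt_fate[2]),
                     "n_other_b": int(ref_fate[3] + alt_fate[3])})
    return rows


def simulate_counts(truth: SimTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate count tables for every baseline and time-course sample.

    Returns ``(counts, sample_map)``; sample ids are ``r{r}_baseline`` and
    ``r{r}_d{day}``, and ``sample_map`` is ready for
    :func:`mipmeter.traits.normalize_to_baseline`.
    """
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    rows, smap = [], []
    for r in range(cfg.replicates):
        sid = f"r{r}_baseline"
        comp = dict(zip(truth.strain_ids, truth.baseline[r]))
        rows += _sample_probe_counts(rng, comp, truth, sid,
                                     cfg.probe_depth_mean, cfg.error_rate)
        smap.append({"sample_id": sid, "replicate": r, "day": cfg.timepoints[0],
                     "is_baseline": True})
        for k, day in enumerate(cfg.timepoints):
            sid = f"r{r}_d{day}"
            comp = dict(zip(truth.strain_ids, truth.frequency[r, :, k]))
            rows += _sample_probe_counts(rng, comp, truth, sid,
                                         cfg.probe_depth_mean, cfg.error_rate)
            smap.append({"sample_id": sid, "replicate": r, "day": day,
                         "is_baseline": False})
    return (pd.DataFrame(rows, columns=["sample_id", "probe_id", "n_ref", "n_alt",
                                        "n_other_a", "n_other_b"]),
            pd.DataFrame(smap))


def simulate_standard_curve(proportions: Sequence[float], config: SimConfig,
                            sample_id: str = "curve") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-sample simulation at a known composition (standard curve / pilot).

    ``proportions`` must sum to 1 (one per strain). Returns ``(counts,
    expected)`` where ``expected`` holds (strain_id, known_proportion).
    Probe biases come from the trajectory stage, so pilots, curves, and time
    courses drawn from the same config share a panel realization.
    """
    props = np.asarray(proportions, dtype=float)
    if props.size != config.n_strains:
        raise ConfigError("need one proportion per strain")
    if not np.isclose(props.sum(), 1.0, atol=1e-9):
        raise ConfigError("proportions must sum to 1")
    truth = simulate_trajectories(config)
    rng = np.random.default_rng([config.seed, 2, zlib.crc32(sample_id.encode())])
    comp = dict(zip(truth.strain_ids, props))
    rows = _sample_probe_counts(rng, comp, truth, sample_id,
                                config.probe_depth_mean, config.error_rate)
    expected = pd.DataFrame({"strain_id": truth.strain_ids,
                             "known_proportion": props})
    return pd.DataFrame(rows), expected


def simulate_equimolar_pilot(config: SimConfig,
                             sample_id: str = "pilot") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equal-proportion single sample used to QC probes against 1/S."""
    props = np.full(config.n_strains, 1.0 / config.n_strains)
    return simulate_standard_curve(props, config, sample_id=sample_id)


# ---------------------------------------------------------------------------
# sequence-level emission

def synthetic_panel(strain_ids: Sequence[str], probes_per_strain: int = 4,
                    seed: int = 0, read_length: int = 50) -> PanelSpec:
    """Construct a random but structurally valid probe panel for sequence-level
    simulations, without needing a genome or VCF.

    Probe ids follow the simulator convention ``{strain}_p{k}`` so panels and
    :class:`SimTruth` objects line up.
    """
    rng = np.random.default_rng([seed, 3])
    bases = np.array(list("ACGT"))
    probes = []
    used_arms: set[str] = set()
    max_scan_idx = read_length - UMI_LENGTH - ARM_LENGTH - 1
    for s, strain in enumerate(strain_ids):
        for k in range(probes_per_strain):
            while True:
                ext = "".join(rng.choice(bases, ARM_LENGTH))
                lig = "".join(rng.choice(bases, ARM_LENGTH))
                if lig not in used_arms:
                    used_arms.add(lig)
                    break
            scan = list("".join(rng.choice(bases, CAPTURE_SIZE)))
            scan_idx = int(rng.integers(0, max_scan_idx + 1))
            ref = scan[scan_idx]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            snv = UniqueSnv(strain_id=strain, chrom=f"sim{s}",
                            pos=1000 * (k + 1) + scan_idx, ref_allele=ref,
                            alt_allele=alt)
            probes.append(MipProbe(
                probe_id=f"{strain}_p{k}", target=snv, extension_arm=ext,
                ligation_arm=lig, scan_seq="".join(scan),
                snv_offset=ARM_LENGTH + scan_idx + 1))
    return PanelSpec(probes_per_strain=probes_per_strain,
                     strains=list(strain_ids), probes=probes)


def write_fastq_from_counts(counts: pd.DataFrame, panel: PanelSpec, path, *,
                            layout: ReadLayout = ReadLayout(), seed: int = 0) -> int:
    """Emit one sample's counts as single-end FASTQ reads.

    Each counted read becomes ``random UMI + ligation arm + scan prefix`` with
    the allele-class base substituted at the SNV slot; read order is shuffled.
    Returns the number of reads written. ``counts`` must contain exactly one
    sample.
    """
    if counts["sample_id"].nunique() != 1:
        raise ValueError("write one sample per FASTQ file")
    rng = np.random.default_rng([seed, 4])
    by_id = {p.probe_id: p for p in panel.probes}
    bases = np.array(list("ACGT"))
    reads = []
    tail_len = layout.read_length - layout.umi_length - layout.arm_length
    for row in counts.itertuples(index=False):
        probe = by_id.get(row.probe_id)
        if probe is None:
            raise ValueError(f"counts reference unknown probe {row.probe_id}")
        snv = probe.target
        oa, ob = other_alleles(snv.ref_allele, snv.alt_allele)
        slot = probe.scan_snv_index
        tail_template = list(probe.scan_seq[:tail_len])
        for base, n in [(snv.ref_allele, row.n_ref), (snv.alt_allele, row.n_alt),
                        (oa, row.n_other_a), (ob, row.n_other_b)]:
            if n == 0:
                continue
            tail_template[slot] = base
            body = probe.ligation_arm + "".join(tail_template)
            umis = rng.choice(bases, size=(n, layout.umi_length))
            reads.extend("".join(u) + body for u in umis)
    rng.shuffle(reads)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@sim_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return len(reads)
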