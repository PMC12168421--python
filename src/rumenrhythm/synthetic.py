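"""Synthetic rumen-microbiome circadian studies with known ground truth.

The generator emulates a time-restricted feeding / transplantation study
design: cows sampled every 6 h over two 24-h cycles (08:00, 14:00, 20:00,
02:00) under five groups — ad libitum (ALF), daytime-restricted (DF),
nighttime-restricted (NF) feeding, and 48 h (RFT2d) / 7 days (RFT7d) after
rumen fluid transplantation.  Each taxon's latent log-abundance is a cosinor
signal plus a per-cow Gaussian random intercept plus i.i.d. Gaussian noise;
relative abundances are obtained by softmax-style closure per sample
(exponentiate, divide by the sample sum).

Ground-truth rhythm classes are imposed through the group-wise cosinor
parameters: FTR taxa shift their peak by exactly +12 h between DF and NF,
MFR taxa by a draw from 3-6 h (outside the 12 +/- 3 h window), GCR taxa are
arrhythmic at RFT2d and rhythmic at RFT7d (LCR the reverse), CCR taxa keep
identical parameters across the transplantation contrast while InCCR taxa
change amplitude and peak.  Because closure distorts relative abundances
(one dominant rhythmic taxon induces apparent anti-phase rhythms in others),
the study retains both the closed abundance tables and the pre-closure
latent tables; truth-recovery checks run on the latent scale where the
ground truth is defined.

Total microbial load (qPCR copies/mL) is itself a cosinor series on the
log10 scale with an evening peak, and fermentation variables are positive
cosinor series with evening VFA peaks and morning pH/NH3-N peaks (shifted
12 h in the NF group); total VFA is always the sum of the six acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError
from .io import GROUPS, AbundanceTable

__all__ = [
    "CLASS_LABELS",
    "GroupRhythm",
    "TaxonTruth",
    "StudyDesign",
    "SyntheticStudy",
    "generate_rhythmic_series",
    "generate_study",
    "generate_fermentation_series",
]

CLASS_LABELS = (
    "FTR",
    "MFR",
    "CCR",
    "InCCR",
    "GCR",
    "LCR",
    "ARRHYTHMIC",
    "NEVER_RHYTHMIC",
    "RHYTHMIC_UNCLASSIFIED",
)

_KINGDOM_PREFIX = {"bacteria": "bac", "archaea": "arc", "protozoa": "pro"}

# Feed becomes available at 08:00 except under nighttime-restricted feeding.
_FEED_START = {"ALF": 8.0, "DF": 8.0, "NF": 20.0, "RFT2d": 8.0, "RFT7d": 8.0}

# log10 copies/mL: kingdom-typical mesor, rhythm amplitude, evening peak.
_QPCR_PARAMS = {"bacteria": (10.5, 0.15, 20.0), "archaea": (8.5, 0.15, 20.0), "protozoa": (5.5, 0.15, 20.0)}
_QPCR_NOISE_SD = 0.05  # log10 units

# Fermentation defaults: variable -> (mesor, amplitude, peak hour).
_FERMENTATION_PARAMS = {
    "acetate": (65.0, 6.0, 18.0),
    "propionate": (20.0, 2.5, 17.5),
    "butyrate": (12.0, 1.5, 18.5),
    "isobutyrate": (1.0, 0.12, 19.0),
    "valerate": (2.0, 0.3, 17.0),
    "isovalerate": (1.5, 0.2, 19.0),
    "ph": (6.2, 0.15, 6.0),
    "nh3n": (12.0, 2.5, 6.5),
}


@dataclass(frozen=True)
class GroupRhythm:
    """True cosinor parameters of one taxon in one group (latent log scale)."""

    mesor: float
    amplitude: float
    peak_time: float
    rhythmic: bool

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")
        if not self.rhythmic and self.amplitude != 0.0:
            raise InvalidParameterError("arrhythmic parameters must have amplitude 0")
        if not (0.0 <= self.peak_time < 24.0):
            raise InvalidParameterError("peak_time must lie in [0, 24)")


@dataclass
class TaxonTruth:
    """Ground truth for one taxon: per-group parameters and intended class."""

    taxon_id: str
    group_params: dict[str, GroupRhythm]
    intended_class: str

    def __post_init__(self):
        if self.intended_class not in CLASS_LABELS:
            raise ConfigurationError(f"unknown class label {self.intended_class!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Study dimensions and noise levels (latent log-abundance scale)."""

    n_cows: int = 12
    groups: tuple[str, ...] = GROUPS
    clock_times: tuple[float, ...] = (2.0, 8.0, 14.0, 20.0)
    n_days: int = 2
    n_taxa: int = 100
    noise_sd: float = 0.25
    cow_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cows, self.n_days, self.n_taxa) < 1:
            raise ConfigurationError("all design counts must be >= 1")
        if self.noise_sd < 0 or self.cow_effect_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if any(not (0.0 <= t < 24.0) for t in self.clock_times):
            raise ConfigurationError("clock_times must lie in [0, 24)")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown groups {sorted(unknown)}")


@dataclass
class SyntheticStudy:
    """A complete generated study with ground truth.

    ``abundance`` holds the closed (relative) tables per kingdom and
    ``latent`` the matching pre-closure log-abundance tables; ``truth``
    records each taxon's true per-group cosinor parameters and class.
    """

    design: StudyDesign
    abundance: dict[str, AbundanceTable]
    latent: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    qpcr: pd.DataFrame
    fermentation: pd.DataFrame
    truth: list[TaxonTruth] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            for g, p in t.group_params.items():
                rows.append(
                    {
                        "taxon_id": t.taxon_id,
                        "group": g,
                        "mesor": p.mesor,
                        "amplitude": p.amplitude,
                        "peak_time": p.peak_time,
                        "rhythmic": p.rhythmic,
                        "class": t.intended_class,
                    }
                )
        return pd.DataFrame(rows)


def generate_rhythmic_series(
    mesor: float,
    amplitude: float,
    peak_time: float,
    times,
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cosinor signal mesor + amplitude*cos(2*pi*(t - peak)/24) + Gaussian noise."""
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    signal = mesor + amplitude * np.cos(2.0 * np.pi * (t - peak_time) / 24.0)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        signal = signal + rng.normal(0.0, noise_sd, size=t.shape)
    return signal


def _base_params(rng: np.random.Generator) -> tuple[float, float, float]:
    """Realistic latent-scale draws: ~10-fold mesor spread, ~e^2-fold swings."""
    mesor = float(rng.normal(0.0, 1.0))
    amplitude = float(rng.uniform(0.75, 1.25))
    peak = float(rng.uniform(0.0, 24.0))
    return mesor, amplitude, peak


def _group_params(label: str, rng: np.random.Generator, groups: tuple[str, ...]) -> dict[str, GroupRhythm]:
    mesor, amp, peak = _base_params(rng)
    flat = GroupRhythm(mesor, 0.0, 0.0, False)
    rhythm = lambda p, a=amp: GroupRhythm(mesor, a, p % 24.0, True)  # noqa: E731

    if label in ("ARRHYTHMIC", "NEVER_RHYTHMIC"):
        params = {g: flat for g in GROUPS}
    elif label == "FTR":
        params = {g: rhythm(peak) for g in GROUPS}
        params["NF"] = rhythm(peak + 12.0)
    elif label == "MFR":
        shift = float(rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 6.0))
        params = {g: rhythm(peak) for g in GROUPS}
        params["NF"] = rhythm(peak + shift)
    elif label == "RHYTHMIC_UNCLASSIFIED":
        params = {g: rhythm(peak) for g in GROUPS}
        params["NF"] = flat
    elif label == "CCR":
        params = {g: rhythm(peak) for g in GROUPS}
    elif label == "InCCR":
        params = {g: rhythm(peak) for g in GROUPS}
        params["RFT7d"] = rhythm(peak + 6.0, amp * 2.0)
    elif label == "GCR":
        params = {g: rhythm(peak) for g in GROUPS}
        params["RFT2d"] = flat
    elif label == "LCR":
        params = {g: rhythm(peak) for g in GROUPS}
        params["RFT7d"] = flat
    else:  # pragma: no cover - guarded by TaxonTruth validation
        raise ConfigurationError(f"unknown class label {label!r}")
    return {g: params[g] for g in groups}


def _make_metadata(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for group in design.groups:
        start = _FEED_START[group]
        for cow in range(1, design.n_cows + 1):
            for day in range(1, design.n_days + 1):
                for clock in design.clock_times:
                    after = (clock - start) % 24.0
                    if after == 0.0:
                        after = 24.0
                    rows.append(
                        {
                            "sample_id": f"{group}_cow{cow:02d}_d{day}_t{clock:04.1f}",
                            "cow_id": f"cow{cow:02d}",
                            "group": group,
                            "clock_time": float(clock),
                            "after_feeding_h": after,
                            "day": day,
                        }
                    )
    return pd.DataFrame(rows)


def generate_study(
    design: StudyDesign,
    class_mix: dict[str, int],
    kingdoms: tuple[str, ...] = ("bacteria", "archaea", "protozoa"),
) -> SyntheticStudy:
    """Generate a complete synthetic study; a pure function of the design seed.

    ``class_mix`` maps class labels to taxon counts and must sum to
    ``design.n_taxa``; the same mix is drawn independently for each kingdom.
    """
    unknown = set(class_mix) - set(CLASS_LABELS)
    if unknown:
        raise ConfigurationError(f"unknown class labels in mix: {sorted(unknown)}")
    if any(c < 0 for c in class_mix.values()):
        raise ConfigurationError("class mix counts must be >= 0")
    if sum(class_mix.values()) != design.n_taxa:
        raise ConfigurationError(
            f"class mix sums to {sum(class_mix.values())}, design.n_taxa is {design.n_taxa}"
        )
    bad_kingdoms = set(kingdoms) - set(_KINGDOM_PREFIX)
    if bad_kingdoms:
        raise ConfigurationError(f"unknown kingdoms {sorted(bad_kingdoms)}")

    root = np.random.SeedSequence(design.seed)
    keys = ("truth", "cow", "noise", "qpcr", "fermentation")
    streams = dict(zip(keys, (np.random.default_rng(s) for s in root.spawn(len(keys)))))

    metadata = _make_metadata(design)
    times = metadata["clock_time"].to_numpy()
    cows = metadata["cow_id"].to_numpy()
    groups_col = metadata["group"].to_numpy()
    n_samples = len(metadata)

    abundance: dict[str, AbundanceTable] = {}
    latent_tables: dict[str, pd.DataFrame] = {}
    truth: list[TaxonTruth] = []

    for kingdom in kingdoms:
        prefix = _KINGDOM_PREFIX[kingdom]
        taxa_truth: list[TaxonTruth] = []
        idx = 0
        for label in sorted(class_mix):
            for _ in range(class_mix[label]):
                idx += 1
                taxa_truth.append(
                    TaxonTruth(
                        taxon_id=f"{prefix}_t{idx:03d}",
                        group_params=_group_params(label, streams["truth"], design.groups),
                        intended_class=label,
                    )
                )

        cow_ids = sorted(set(cows))
        cow_fx = {
            (t.taxon_id, c): streams["cow"].normal(0.0, design.cow_effect_sd)
            for t in taxa_truth
            for c in cow_ids
        }

        latent = np.empty((n_samples, len(taxa_truth)))
        for j, t in enumerate(taxa_truth):
            col = np.empty(n_samples)
            for g in design.groups:
                mask = groups_col == g
                p = t.group_params[g]
                col[mask] = generate_rhythmic_series(
                    p.mesor, p.amplitude, p.peak_time, times[mask], 0.0
                )
            col += np.array([cow_fx[(t.taxon_id, c)] for c in cows])
            if design.noise_sd > 0:
                col += streams["noise"].normal(0.0, design.noise_sd, size=n_samples)
            latent[:, j] = col

        taxon_ids = [t.taxon_id for t in taxa_truth]
        latent_df = pd.DataFrame(latent, index=metadata["sample_id"], columns=taxon_ids)
        closed = np.exp(latent)
        closed = closed / closed.sum(axis=1, keepdims=True)
        abundance[kingdom] = AbundanceTable(
            pd.DataFrame(closed, index=metadata["sample_id"], columns=taxon_ids),
            mode="fractions",
        )
        latent_tables[kingdom] = latent_df
        truth.extend(taxa_truth)

    qpcr_rows = []
    for kingdom in kingdoms:
        mesor, amp, peak = _QPCR_PARAMS[kingdom]
        log10_load = generate_rhythmic_series(mesor, amp, peak, times, 0.0)
        log10_load = log10_load + streams["qpcr"].normal(0.0, _QPCR_NOISE_SD, size=n_samples)
        for sid, v in zip(metadata["sample_id"], 10.0**log10_load):
            qpcr_rows.append({"sample_id": sid, "kingdom": kingdom, "total_copies_per_ml": v})
    qpcr = pd.DataFrame(qpcr_rows)

    fermentation = generate_fermentation_series(metadata, rng=streams["fermentation"])

    return SyntheticStudy(
        design=design,
        abundance=abundance,
        latent=latent_tables,
        metadata=metadata,
        qpcr=qpcr,
        fermentation=fermentation,
        truth=truth,
    )


def generate_fermentation_series(
    metadata: pd.DataFrame,
    peak_map: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    noise_frac: float = 0.05,
) -> pd.DataFrame:
    """Positive cosinor fermentation series for every sample in ``metadata``.

    ``peak_map`` overrides the default peak hours per variable (VFA peaks in
    the evening, pH/NH3-N about 12 h opposed); the nighttime-restricted group
    has all peaks shifted by 12 h.  Noise SD is ``noise_frac`` times each
    variable's amplitude; TVFA is computed as the sum of the six VFAs.
    """
    peak_map = dict(peak_map or {})
    for var, hour in peak_map.items():
        if var not in _FERMENTATION_PARAMS:
            raise InvalidParameterError(f"unknown fermentation variable {var!r}")
        if not (0.0 <= hour < 24.0):
            raise InvalidParameterError(f"peak hour {hour} for {var!r} outside [0, 24)")
    if noise_frac < 0:
        raise InvalidParameterError("noise_frac must be >= 0")
    rng = np.random.default_rng(rng)

    times = metadata["clock_time"].to_numpy(dtype=float)
    nf_shift = np.where(metadata["group"].to_numpy() == "NF", 12.0, 0.0)
    out = pd.DataFrame({"sample_id": metadata["sample_id"].to_numpy()})
    for var, (mesor, amp, default_peak) in _FERMENTATION_PARAMS.items():
        peak = peak_map.get(var, default_peak)
        series = mesor + amp * np.cos(2.0 * np.pi * (times - (peak + nf_shift)) / 24.0)
        if noise_frac > 0:
            series = series + rng.normal(0.0, noise_frac * amp, size=times.shape)
        out[var] = np.maximum(series, 0.01 * mesor)
    vfa_cols = ["acetate", "propionate", "butyrate", "isobutyrate", "valerate", "isovalerate"]
    out["tvfa"] = out[vfa_cols].sum(axis=1)
    return out
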