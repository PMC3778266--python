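"""Synthetic amyloid-stratified cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: three diagnostic groups (amyloid-negative normals CN-, amyloid-
positive normals CN+, and amyloid-positive MCI/AD as a positive control with
a known atrophy signature), per-ROI group atrophy effects, two-plus noisy
measurement "techniques" observing the same latent signal, demographic
covariates, per-technique intracranial volume, and a continuous global
amyloid tracer ratio concentrated below/above the 1.5 positivity cut-point
per group.

The measurement model is a single-factor latent model.  For subject *i* in
group *g*, ROI *r*:

    a_ir = -delta[g, r] + z_ir,          z ~ N(0, 1)   (latent atrophy axis)
    s_irt = lambda_t * a_ir + sqrt(1 - lambda_t^2) * e_irt,   e ~ N(0, 1)

with ``e`` independent across channels, so delta > 0 means a *smaller*
observed measure (atrophy) and each channel's loading ``lambda_t`` sets the
ceiling on cross-technique agreement.  Observed measures are an affine
rescaling of ``s`` into plausible units (mm for thickness; mm3 for volume,
scaled by the subject's TIV so that TIV normalization downstream recovers the
standardized signal).  The closed-form group-separation AUROC for this model,
``true_auroc``, is Phi(lambda * delta / sqrt(2)).

No generative model is published for the real data; every distributional
choice here is a documented stand-in (see docs/methods.md), not an estimate
of the source cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .harmonize import MeasurementTable, ROIMap, default_roi_map, parse_column_names

__all__ = [
    "GROUPS",
    "ChannelSpec",
    "SimConfig",
    "simulate_cohort",
    "true_auroc",
    "generic_roi_map",
    "write_cohort",
    "load_cohort",
]

GROUPS = ("CN_NEG", "CN_POS", "MCI_AD_POS")

#: Master ROI names of the packaged 28-ROI harmonized set.
DEFAULT_ROI_NAMES = (
    "entorhinal", "hippocampus", "amygdala", "parahippocampal", "temporal_pole",
    "superior_temporal", "middle_temporal", "inferior_temporal", "fusiform",
    "transverse_temporal", "insula", "superior_frontal", "middle_frontal",
    "pars_opercularis", "pars_triangularis", "pars_orbitalis",
    "medial_orbitofrontal", "lateral_orbitofrontal", "precentral", "paracentral",
    "anterior_cingulate", "posterior_cingulate", "postcentral",
    "superior_parietal", "inferior_parietal", "supramarginal", "precuneus",
    "lateral_occipital",
)

# Weak, spatially scattered effects in amyloid-positive normals...
_DELTA_CN_POS = (
    0.10, 0.20, 0.05, 0.05, 0.05, 0.05, 0.10, 0.10, 0.20, 0.00, 0.05, 0.05,
    0.15, 0.15, 0.15, 0.05, 0.20, 0.15, 0.00, 0.00, 0.05, 0.15, 0.00, 0.05,
    0.10, 0.20, 0.15, 0.00,
)
# ...versus a strong medial/lateral-temporal + parietal signature in MCI/AD.
_DELTA_MCI_AD = (
    1.30, 1.20, 1.00, 0.80, 0.70, 0.70, 1.10, 1.10, 0.90, 0.20, 0.50, 0.40,
    0.50, 0.40, 0.40, 0.40, 0.50, 0.50, 0.15, 0.15, 0.40, 0.80, 0.20, 0.60,
    1.00, 0.80, 0.90, 0.30,
)

#: Plausible mean cortical thickness (mm) and bilateral volume (mm3) per ROI.
DEFAULT_THICKNESS_MM = {
    "entorhinal": 3.3, "parahippocampal": 2.8, "temporal_pole": 3.6,
    "superior_temporal": 2.8, "middle_temporal": 2.9, "inferior_temporal": 2.8,
    "fusiform": 2.7, "transverse_temporal": 2.4, "insula": 3.0,
    "superior_frontal": 2.7, "middle_frontal": 2.5, "pars_opercularis": 2.6,
    "pars_triangularis": 2.5, "pars_orbitalis": 2.7, "medial_orbitofrontal": 2.4,
    "lateral_orbitofrontal": 2.6, "precentral": 2.5, "paracentral": 2.4,
    "anterior_cingulate": 2.8, "posterior_cingulate": 2.5, "postcentral": 2.1,
    "superior_parietal": 2.2, "inferior_parietal": 2.4, "supramarginal": 2.5,
    "precuneus": 2.3, "lateral_occipital": 2.2,
}
DEFAULT_VOLUME_MM3 = {
    "entorhinal": 3500, "hippocampus": 7400, "amygdala": 3100,
    "parahippocampal": 4100, "temporal_pole": 4500, "superior_temporal": 22000,
    "middle_temporal": 20000, "inferior_temporal": 18000, "fusiform": 17000,
    "transverse_temporal": 2100, "insula": 13000, "superior_frontal": 44000,
    "middle_frontal": 38000, "pars_opercularis": 8200, "pars_triangularis": 7500,
    "pars_orbitalis": 4400, "medial_orbitofrontal": 10500,
    "lateral_orbitofrontal": 14500, "precentral": 26000, "paracentral": 7300,
    "anterior_cingulate": 8600, "posterior_cingulate": 9000, "postcentral": 20000,
    "superior_parietal": 24000, "inferior_parietal": 26000,
    "supramarginal": 18500, "precuneus": 18000, "lateral_occipital": 22000,
}
_FALLBACK_THICKNESS = 2.5
_FALLBACK_VOLUME = 12000.0
_THICKNESS_SD = 0.15  # mm, between-subject
_VOLUME_CV = 0.09  # between-subject coefficient of variation
_TIV_REF = 1.45e6  # mm3 reference head size


@dataclass(frozen=True)
class ChannelSpec:
    """One observation channel: a technique name (keys the ROI map), its
    loading on the latent atrophy factor, and which TIV it uses."""

    technique: str
    lam: float
    tiv_key: str

    def __post_init__(self) -> None:
        if not 0 <= self.lam <= 1:
            raise ConfigError(f"lambda_tech for {self.technique!r} must be in [0, 1], got {self.lam}")


DEFAULT_CHANNELS = (
    ChannelSpec("freesurfer", 0.7, "freesurfer"),
    ChannelSpec("freesurfer_volume", 0.7, "freesurfer"),
    ChannelSpec("spm", 0.7, "spm"),
)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic cohort.

    Group order throughout is (CN-, CN+, MCI/AD+); CN- is the reference
    group with zero effect.  ``delta`` has one row per non-reference group
    and one column per ROI, in standardized latent units; positive delta
    lowers the observed measure (atrophy).
    """

    n_per_group: tuple[int, int, int] = (215, 115, 88)
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    delta: np.ndarray | None = None
    channels: tuple[ChannelSpec, ...] = DEFAULT_CHANNELS
    # covariates, per group (CN-, CN+, MCI/AD+)
    age_mean: tuple = (80.0, 79.5, 78.0)
    age_sd: tuple = (5.0, 6.0, 7.5)
    p_female: tuple = (0.45, 0.43, 0.47)
    education_mean: tuple = (14.5, 14.8, 14.0)
    education_sd: tuple = (2.5, 2.6, 2.9)
    # amyloid tracer ratio: truncated normal per group
    pib_loc: tuple = (1.25, 1.85, 2.10)
    pib_scale: tuple = (0.09, 0.30, 0.35)
    pib_bounds: tuple = ((1.02, 1.495), (1.505, 3.0), (1.55, 3.5))
    #: optional coupling of pib_ratio to the subject's mean latent atrophy
    #: burden (0 = independent, the default null-like scenario)
    pib_atrophy_coupling: float = 0.0
    # intracranial volume model
    tiv_mean: float = _TIV_REF
    tiv_sd: float = 1.3e5
    tiv_male_factor: float = 1.12
    tiv_cross_sd: float = 0.045  # log-scale sd between techniques' TIV estimates
    # sub-ROI disaggregation noise
    hemi_thickness_sd: float = 0.03  # mm, hemisphere-level deviation
    area_cv: float = 0.15  # lognormal cv of per-subject surface areas
    volume_split_jitter: float = 0.08  # spread of fixed sub-ROI volume fractions
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 2 for n in self.n_per_group):
            raise ConfigError(f"n_per_group must be 3 counts >= 2, got {self.n_per_group}")
        if len(self.roi_names) < 1:
            raise ConfigError("roi_names must name at least one ROI")
        if self.delta is not None:
            d = np.asarray(self.delta, dtype=float)
            if d.shape != (2, len(self.roi_names)):
                raise ConfigError(
                    f"delta must have shape (2, {len(self.roi_names)}), got {d.shape}"
                )
        if not self.channels:
            raise ConfigError("channels must list at least one observation channel")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def delta_matrix(self) -> np.ndarray:
        """(3, R) effect matrix including the zero CN- reference row."""
        if self.delta is not None:
            d = np.asarray(self.delta, dtype=float)
        elif self.roi_names == DEFAULT_ROI_NAMES:
            d = np.array([_DELTA_CN_POS, _DELTA_MCI_AD])
        else:
            d = np.zeros((2, self.n_rois))
        return np.vstack([np.zeros(self.n_rois), d])


def true_auroc(delta_scalar: float, lambda_scalar: float) -> float:
    """Closed-form AUROC separating reference from an affected group.

    Under the latent model the observed difference between a reference and an
    affected subject is N(lambda*delta, 2), so P(reference > affected) =
    Phi(lambda*delta/sqrt(2)).
    """
    if not 0 <= lambda_scalar <= 1:
        raise ConfigError(f"lambda must be in [0, 1], got {lambda_scalar}")
    return float(stats.norm.cdf(lambda_scalar * delta_scalar / np.sqrt(2)))


def generic_roi_map(roi_names, channels=DEFAULT_CHANNELS) -> ROIMap:
    """Left/right identity map for arbitrary ROI names.

    Each master ROI maps to one same-named sub-ROI per hemisphere; kind is
    thickness for techniques named like the surface channel ('freesurfer'),
    volume otherwise.
    """
    rows = []
    for ch in channels:
        kind = "thickness" if ch.technique == "freesurfer" else "volume"
        for roi in roi_names:
            for hemi in ("left", "right"):
                rows.append((roi, ch.technique, roi, hemi, kind))
    return ROIMap(
        pd.DataFrame(rows, columns=["master_roi", "technique", "sub_roi", "hemisphere", "measure_kind"])
    )


def _resolve_map(config: SimConfig, roi_map: ROIMap | None) -> ROIMap:
    if roi_map is not None:
        return roi_map
    if config.roi_names == DEFAULT_ROI_NAMES:
        return default_roi_map()
    return generic_roi_map(config.roi_names, config.channels)


def _truncnorm(rng, loc, scale, lo, hi, size):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def simulate_cohort(
    config: SimConfig, roi_map: ROIMap | None = None
) -> tuple[pd.DataFrame, dict[str, MeasurementTable]]:
    """Draw one synthetic cohort.

    Returns ``(subjects, tables)`` where ``subjects`` is a DataFrame indexed
    by subject_id with columns group, clinical, pib_ratio, age, sex,
    education, tiv_freesurfer, tiv_spm, and ``tables`` maps each channel's
    technique name to its sub-ROI :class:`MeasurementTable`.  Bit-identical
    under a fixed config (same seed included).
    """
    roi_map = _resolve_map(config, roi_map)
    rng = np.random.default_rng(config.seed)
    n_total = sum(config.n_per_group)
    group_idx = np.repeat([0, 1, 2], config.n_per_group)
    subject_ids = [f"S{i + 1:04d}" for i in range(n_total)]

    # --- covariates -------------------------------------------------------
    age = np.empty(n_total)
    edu = np.empty(n_total)
    sex = np.empty(n_total, dtype=object)
    pib = np.empty(n_total)
    for g in range(3):
        m = group_idx == g
        n_g = m.sum()
        age[m] = np.clip(rng.normal(config.age_mean[g], config.age_sd[g], n_g), 40, 100)
        edu[m] = np.clip(np.round(rng.normal(config.education_mean[g], config.education_sd[g], n_g)), 6, 20)
        sex[m] = np.where(rng.random(n_g) < config.p_female[g], "F", "M")
        lo, hi = config.pib_bounds[g]
        pib[m] = _truncnorm(rng, config.pib_loc[g], config.pib_scale[g], lo, hi, n_g)

    is_male = sex == "M"
    tiv_base = np.clip(rng.normal(config.tiv_mean, config.tiv_sd, n_total), 9e5, 2.2e6)
    tiv_fs = tiv_base * np.where(is_male, config.tiv_male_factor, 1.0)
    tiv_spm = tiv_fs * np.exp(rng.normal(0.0, config.tiv_cross_sd, n_total))

    # --- latent atrophy and channel signals -------------------------------
    delta = config.delta_matrix()  # (3, R)
    latent = -delta[group_idx] + rng.standard_normal((n_total, config.n_rois))
    if config.pib_atrophy_coupling:
        burden = -latent.mean(axis=1)
        pib = np.clip(pib + config.pib_atrophy_coupling * burden, 0.6, None)

    tiv_by_key = {"freesurfer": tiv_fs, "spm": tiv_spm}
    tables: dict[str, MeasurementTable] = {}
    for ch in config.channels:
        noise = rng.standard_normal((n_total, config.n_rois))
        signal = ch.lam * latent + np.sqrt(1.0 - ch.lam**2) * noise
        entries = roi_map.for_technique(ch.technique)
        tiv_ratio = tiv_by_key[ch.tiv_key] / _TIV_REF
        cols: dict[str, np.ndarray] = {}
        for r, roi in enumerate(config.roi_names):
            ent = entries[entries["master_roi"] == roi]
            if ent.empty:
                raise ConfigError(
                    f"roi_names: ROI {roi!r} has no map entries for technique {ch.technique!r}"
                )
            kind = ent["measure_kind"].iloc[0]
            if kind == "thickness":
                mu = DEFAULT_THICKNESS_MM.get(roi, _FALLBACK_THICKNESS)
                master = mu + _THICKNESS_SD * signal[:, r]
                mu_vol = DEFAULT_VOLUME_MM3.get(roi, _FALLBACK_VOLUME)
                base_area = mu_vol / (2.0 * mu)  # per-hemisphere patch area, mm2
                for sub, hemi in zip(ent["sub_roi"], ent["hemisphere"]):
                    cols[f"{sub}_{hemi}_thickness"] = np.clip(
                        master + rng.normal(0.0, config.hemi_thickness_sd, n_total), 0.5, None
                    )
                    sigma_log = np.sqrt(np.log1p(config.area_cv**2))
                    cols[f"{sub}_{hemi}_area"] = base_area * np.exp(
                        rng.normal(0.0, sigma_log, n_total)
                    )
            else:
                mu = DEFAULT_VOLUME_MM3.get(roi, _FALLBACK_VOLUME)
                master = tiv_ratio * np.clip(
                    mu * (1.0 + _VOLUME_CV * signal[:, r]), 0.2 * mu, None
                )
                k = len(ent)
                w = 1.0 / k + config.volume_split_jitter * rng.uniform(-1.0 / k, 1.0 / k, k)
                w = np.clip(w, 0.05 / k, None)
                w = w / w.sum()
                for j, (sub, hemi) in enumerate(zip(ent["sub_roi"], ent["hemisphere"])):
                    cols[f"{sub}_{hemi}_volume"] = w[j] * master
        values = pd.DataFrame(cols, index=pd.Index(subject_ids, name="subject_id"))
        tables[ch.technique] = MeasurementTable(technique=ch.technique, values=values)

    subjects = pd.DataFrame(
        {
            "group": np.asarray(GROUPS)[group_idx],
            "clinical": np.where(group_idx == 2, "MCI_AD", "CN"),
            "pib_ratio": pib,
            "age": age,
            "sex": sex,
            "education": edu,
            "tiv_freesurfer": tiv_fs,
            "tiv_spm": tiv_spm,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    return subjects, tables


def write_cohort(outdir, subjects: pd.DataFrame, tables: dict[str, MeasurementTable]) -> None:
    """Write the standard cohort CSVs: subjects.csv plus one table per technique."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(outdir / "subjects.csv", index_label="subject_id")
    for tech, table in tables.items():
        table.to_csv(outdir / f"measurements_{tech}.csv")


def load_cohort(indir) -> tuple[pd.DataFrame, dict[str, MeasurementTable]]:
    """Read back a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    indir = Path(indir)
    subjects = pd.read_csv(indir / "subjects.csv", index_col="subject_id")
    tables = {}
    for path in sorted(indir.glob("measurements_*.csv")):
        tech = path.stem.removeprefix("measurements_")
        values = pd.read_csv(path, index_col="subject_id")
        tables[tech] = MeasurementTable(
            technique=tech, values=values, columns=parse_column_names(values.columns)
        )
    return subjects, tables
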