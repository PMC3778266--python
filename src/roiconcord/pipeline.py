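"""End-to-end study orchestration.

Runs the full ROI-concordance analysis: obtain a cohort (simulate or load),
harmonize each technique's sub-ROI measurements onto the master ROI set,
classify amyloid status from the continuous tracer ratio, build the
propensity-matched amyloid-negative comparison set, compute per-ROI
AUROC/rank tables with bootstrap rank CIs for every group comparison and
technique, measure cross-technique rank concordance (CCC) and per-ROI
Spearman correlations, and repeat the analysis under the sensitivity
variants (lower cut-point, borderline-band exclusion, volume-for-thickness
substitution).

Everything is deterministic given the config: stage seeds are derived from
the single top-level seed, and the sensitivity variants reuse the primary
matching/bootstrap seed derivation, so a variant whose rule equals the
primary rule reproduces the primary outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .bootstrap import BootstrapConfig, bootstrap_rank_ci
from .concordance import ConcordanceReport, cross_technique_spearman, rank_concordance
from .discrimination import RankTable, rank_table
from .errors import ConfigError, DataError
from .harmonize import MeasurementTable, ROIMap, harmonize
from .select import (
    CutpointRule,
    MatchResult,
    classify_amyloid,
    fit_propensity,
    match_one_to_one,
)
from .simulate import SimConfig, _resolve_map, load_cohort, simulate_cohort

__all__ = ["StudyConfig", "StudyReport", "Variant", "run_study", "cohort_summary", "write_report"]

log = logging.getLogger("roiconcord")

COMPARISONS = (("CN_NEG", "CN_POS"), ("CN_NEG", "MCI_AD_POS"), ("CN_POS", "MCI_AD_POS"))


@dataclass(frozen=True)
class Variant:
    """One sensitivity analysis: a relabeled rule and/or channel substitution."""

    name: str
    rule: CutpointRule
    channel_pair: tuple[str, str] | None = None


def default_variants(primary_rule: CutpointRule) -> tuple[Variant, ...]:
    return (
        Variant("cutpoint_1.4", CutpointRule(1.4)),
        Variant("exclude_1.3_1.5", CutpointRule(1.5, (1.3, 1.5))),
        Variant("freesurfer_volume", primary_rule, ("freesurfer_volume", "spm")),
    )


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full study run.

    Exactly one of ``sim`` / ``input_dir`` provides the cohort.  The primary
    analysis compares the channel pair (default FreeSurfer-style thickness vs
    SPM-style volume); ``variants`` defaults to the three standard
    sensitivity analyses.
    """

    sim: SimConfig | None = None
    input_dir: str | None = None
    rule: CutpointRule = CutpointRule(1.5)
    bootstrap: BootstrapConfig = BootstrapConfig()
    channel_pair: tuple[str, str] = ("freesurfer", "spm")
    comparisons: tuple = COMPARISONS
    variants: tuple[Variant, ...] | None = None
    match_covariates: tuple[str, ...] = ("age", "sex", "education")
    mci_uses_matched: bool = True
    roi_map: ROIMap | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ConfigError("exactly one of sim / input_dir must be given")
        for a, b in self.comparisons:
            for g in (a, b):
                if g not in ("CN_NEG", "CN_POS", "MCI_AD_POS"):
                    raise ConfigError(f"comparisons reference unknown group {g!r}")

    def resolved_variants(self) -> tuple[Variant, ...]:
        if self.variants is None:
            return default_variants(self.rule)
        return self.variants


@dataclass
class StudyReport:
    """All tabular outputs of one analysis pass (primary or one variant)."""

    label: str
    groups: dict[str, list[str]]
    match: MatchResult
    rank_tables: dict[tuple[str, str], RankTable]
    concordance: dict[str, ConcordanceReport]
    spearman_per_roi: pd.Series
    spearman_median: float
    spearman_range: tuple[float, float]
    summary: pd.DataFrame | None = None
    variants: dict[str, "StudyReport"] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def ccc(self, group_a: str, group_b: str) -> float:
        return self.concordance[f"{group_a} vs {group_b}"].ccc


def _pct(n_sub: int, n_tot: int) -> int:
    return int(np.floor(100.0 * n_sub / n_tot + 0.5))


def cohort_summary(subjects: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Demographics table: n, females (%), median (range) age/education per
    group, with rank-sum / chi-square p-values against the reference group.

    Mirrors the usual participant-demographics layout: continuous covariates
    as median (min, max) compared by Wilcoxon rank-sum, counts compared by
    Pearson chi-square.
    """
    labels = list(groups)
    for lab in labels:
        if len(groups[lab]) == 0:
            raise DataError(f"group {lab!r} is empty")
    sub = {lab: subjects.loc[groups[lab]] for lab in labels}

    out: dict[str, dict] = {}
    for lab in labels:
        s = sub[lab]
        n = len(s)
        n_f = int((s["sex"] == "F").sum())
        out[lab] = {
            "n": n,
            "n_female": n_f,
            "pct_female": _pct(n_f, n),
            "age_median": s["age"].median(),
            "age_min": s["age"].min(),
            "age_max": s["age"].max(),
            "education_median": s["education"].median(),
            "education_min": s["education"].min(),
            "education_max": s["education"].max(),
        }
    table = pd.DataFrame(out)

    ref = labels[0]
    for lab in labels[1:]:
        a, b = sub[ref], sub[lab]
        pvals = {
            "age_median": stats.ranksums(a["age"], b["age"]).pvalue,
            "education_median": stats.ranksums(a["education"], b["education"]).pvalue,
        }
        counts = np.array(
            [
                [(a["sex"] == "F").sum(), (a["sex"] == "M").sum()],
                [(b["sex"] == "F").sum(), (b["sex"] == "M").sum()],
            ]
        )
        pvals["pct_female"] = stats.chi2_contingency(counts).pvalue
        col = f"p_{ref}_vs_{lab}"
        table[col] = pd.Series(pvals)
    return table


def assign_groups(subjects: pd.DataFrame, rule: CutpointRule) -> dict[str, list[str]]:
    """Amyloid-classify the cohort under a cut-point rule.

    Clinically normal subjects become CN-/CN+ by their tracer ratio
    (band-excluded subjects are dropped); MCI/AD subjects are retained only
    if they classify amyloid-positive.
    """
    status = pd.Series(
        classify_amyloid(subjects["pib_ratio"].to_numpy(), rule), index=subjects.index
    )
    cn = subjects["clinical"] == "CN"
    groups = {
        "CN_NEG": list(subjects.index[cn & (status == "negative")]),
        "CN_POS": list(subjects.index[cn & (status == "positive")]),
        "MCI_AD_POS": list(subjects.index[~cn & (status == "positive")]),
    }
    n_excl = int((status == "excluded").sum())
    log.info(
        "group assignment (cut=%s band=%s): CN-=%d CN+=%d MCI/AD+=%d excluded=%d",
        rule.cutpoint, rule.exclusion_band,
        len(groups["CN_NEG"]), len(groups["CN_POS"]), len(groups["MCI_AD_POS"]), n_excl,
    )
    return groups


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(3)
    return {k: int(v & 0x7FFFFFFF) for k, v in zip(("sim", "match", "boot"), state)}


def _table_seed(boot_seed: int, label: str) -> int:
    return (boot_seed ^ zlib.crc32(label.encode())) & 0x7FFFFFFF


def _analysis_pass(
    label: str,
    subjects: pd.DataFrame,
    harmonized: dict[str, MeasurementTable],
    rule: CutpointRule,
    channel_pair: tuple[str, str],
    config: StudyConfig,
    seeds: dict[str, int],
) -> StudyReport:
    groups = assign_groups(subjects, rule)
    for g in ("CN_NEG", "CN_POS", "MCI_AD_POS"):
        if len(groups[g]) < 2:
            raise DataError(f"group {g} has fewer than 2 subjects after classification")

    # propensity-matched CN- comparison set
    cn_ids = groups["CN_NEG"] + groups["CN_POS"]
    cn = subjects.loc[cn_ids]
    treated = pd.Series(cn.index.isin(groups["CN_POS"]), index=cn.index)
    prop = fit_propensity(cn, treated, config.match_covariates)
    match = match_one_to_one(prop, groups["CN_POS"], groups["CN_NEG"], seed=seeds["match"])
    log.info("%s: matched %d CN+/CN- pairs (%d unmatched)", label, len(match.pairs), len(match.unmatched))

    analysis_groups = dict(groups)
    analysis_groups["CN_NEG"] = match.control_ids

    def members(g: str, comparison: tuple[str, str]) -> list[str]:
        if g == "CN_NEG" and "MCI_AD_POS" in comparison and not config.mci_uses_matched:
            return groups["CN_NEG"]
        return analysis_groups[g]

    rank_tables: dict[tuple[str, str], RankTable] = {}
    reports: dict[str, ConcordanceReport] = {}
    for comp in config.comparisons:
        g_a, g_b = comp
        comp_label = f"{g_a} vs {g_b}"
        per_tech: list[RankTable] = []
        for tech in channel_pair:
            vals = harmonized[tech].values
            va = vals.loc[members(g_a, comp)]
            vb = vals.loc[members(g_b, comp)]
            rt = rank_table(va, vb, group_a=g_a, group_b=g_b, technique=tech)
            boot_cfg = replace(
                config.bootstrap, seed=_table_seed(seeds["boot"], f"{comp_label}|{tech}")
            )
            ci = bootstrap_rank_ci(va, vb, boot_cfg)
            rt.table["ci_low"] = ci["ci_low"]
            rt.table["ci_high"] = ci["ci_high"]
            rank_tables[(comp_label, tech)] = rt
            per_tech.append(rt)
        reports[comp_label] = rank_concordance(per_tech[0], per_tech[1], label=comp_label)

    # pooled cross-technique agreement over all analysis subjects
    all_ids = sorted(set().union(*[analysis_groups[g] for g in ("CN_NEG", "CN_POS", "MCI_AD_POS")]))
    t1, t2 = channel_pair
    rho, rho_med, rho_rng = cross_technique_spearman(
        harmonized[t1].values.loc[all_ids], harmonized[t2].values.loc[all_ids]
    )
    for comp_label, rep in reports.items():
        rep.spearman_per_roi = rho
        rep.spearman_median = rho_med
        rep.spearman_range = rho_rng

    return StudyReport(
        label=label,
        groups=analysis_groups,
        match=match,
        rank_tables=rank_tables,
        concordance=reports,
        spearman_per_roi=rho,
        spearman_median=rho_med,
        spearman_range=rho_rng,
    )


def _config_digest(config: StudyConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, ROIMap):
            return obj.entries.to_csv(index=False)
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    blob = json.dumps(enc(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_study(config: StudyConfig) -> StudyReport:
    """Run the primary analysis and all sensitivity variants.

    Returns the primary :class:`StudyReport` with ``variants`` populated and
    a manifest recording the config digest, seed and package version.  If
    ``config.output_dir`` is set, all tables are written there as CSV/JSON.
    """
    seeds = _stage_seeds(config.seed)
    if config.sim is not None:
        sim = replace(config.sim, seed=seeds["sim"]) if config.sim.seed == 0 else config.sim
        subjects, tables = simulate_cohort(sim)
        roi_map = config.roi_map or _resolve_map(sim, None)
    else:
        subjects, tables = load_cohort(config.input_dir)
        roi_map = config.roi_map
        if roi_map is None:
            from .harmonize import default_roi_map

            roi_map = default_roi_map()

    needed = set(config.channel_pair)
    for var in config.resolved_variants():
        if var.channel_pair:
            needed.update(var.channel_pair)
    missing = needed - set(tables)
    if missing:
        raise DataError(f"measurement tables missing for channels: {sorted(missing)}")

    harmonized = {}
    for tech in sorted(needed):
        tiv_col = "tiv_freesurfer" if tech.startswith("freesurfer") else "tiv_spm"
        harmonized[tech] = harmonize(tables[tech], roi_map, subjects[tiv_col])
        log.info("harmonized %s: %d master ROIs", tech, harmonized[tech].values.shape[1])

    report = _analysis_pass(
        "primary", subjects, harmonized, config.rule, config.channel_pair, config, seeds
    )
    report.summary = cohort_summary(subjects, report.groups)

    for var in config.resolved_variants():
        pair = var.channel_pair or config.channel_pair
        report.variants[var.name] = _analysis_pass(
            var.name, subjects, harmonized, var.rule, pair, config, seeds
        )

    report.manifest = {
        "package": "roiconcord",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_sha256": _config_digest(config),
        "n_subjects": int(len(subjects)),
        "channel_pair": list(config.channel_pair),
        "variants": [v.name for v in config.resolved_variants()],
    }
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def write_report(report: StudyReport, outdir) -> None:
    """Write every table of a study report (and its variants) as CSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (comp, tech), rt in report.rank_tables.items():
        slug = comp.replace(" ", "_")
        rt.to_csv(outdir / f"ranks_{slug}_{tech}.csv")
    conc_rows = []
    for comp, rep in report.concordance.items():
        slug = comp.replace(" ", "_")
        pairs = rep.rank_pairs.copy()
        pairs["spearman_rho"] = rep.spearman_per_roi
        pairs.to_csv(outdir / f"concordance_{slug}.csv", index_label="roi")
        conc_rows.append(rep.to_dict())
    (outdir / "concordance.json").write_text(json.dumps(conc_rows, indent=2))
    if report.summary is not None:
        report.summary.to_csv(outdir / "cohort_summary.csv", index_label="statistic")
    report.match.to_frame().to_csv(outdir / "matched_pairs.csv", index=False)
    if report.manifest:
        (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
    for name, var in report.variants.items():
        write_report(var, outdir / f"variant_{name}")
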