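"""End-to-end pipeline over a fully synthetic cohort.

Stages: simulate -> qpadm -> models -> pca -> relatedness -> diversity
-> report.  Every stage is a pure function of (inputs, config, seed);
rerunning with the same config and seed reproduces outputs byte for
byte.  The default configuration exercises every analysis on a small
cohort generated from the bundled drift tree, so the whole pipeline
runs on one CPU in a few minutes.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eigenstrat import GenotypeTable, read_eigenstrat, write_eigenstrat
from .fstats import BlockScheme, F4Engine, qpadm_fit
from .haplogroups import site_haplogroup_diversity
from .model_search import (
    CORE_RIGHTS,
    PROXY_SOURCES,
    build_report,
    default_schemes,
    enumerate_models,
)
from .pca import cline_fraction, fit_pca, project, project_reference, site_diversity
from .relatedness import (
    IbdSummary,
    baseline_b,
    classify_pair,
    kinship_r,
    pairwise_mismatch,
    roh_summarize,
    segment_age,
)
from .synthetic import (
    AdmixtureSpec,
    PopulationTree,
    assign_haplogroups,
    cousin_offspring_pedigree,
    draw_frequencies,
    make_cohort,
    make_snp_table,
    sibling_pedigree,
    simulate_pedigree,
)

log = logging.getLogger("adnapop.pipeline")

STAGES = ("simulate", "qpadm", "models", "pca", "relatedness", "diversity", "report")


class PipelineConfigError(ValueError):
    """Raised before any compute when the configuration is invalid."""


def default_tree() -> PopulationTree:
    """Bundled drift tree relating the 8 proxy sources and 14 right
    populations.

    Each grouped ancestry component has at least one "sister" right
    population sharing internal drift with it, so the rights are
    informative about which component a target carries; the two members
    within the Sicilian-Aegean and western-Mediterranean pairs share
    their terminal node and remain nearly indistinguishable, as in real
    panels.  Edge F values are of the order of within-continental
    ancient differentiation (0.01-0.12).
    """
    edges = [
        # deep, broadly symmetric rights
        ("root", "El_Miron", 0.06),
        ("root", "Ust_Ishim", 0.08),
        ("root", "Kostenki", 0.07),
        ("root", "GoyetQ116", 0.07),
        ("root", "Vestonice", 0.07),
        ("root", "MA1", 0.08),
        ("root", "Mota", 0.12),
        # western Eurasian forager branch
        ("root", "WEur", 0.02),
        ("WEur", "AegSide", 0.01),
        ("AegSide", "Villabruna", 0.03),
        ("AegSide", "Aegean", 0.012),
        ("Aegean", "Greece_BA", 0.015),
        ("Aegean", "Sicily_EMBA", 0.015),
        ("WEur", "WestSide", 0.01),
        ("WestSide", "WHG", 0.03),
        ("WestSide", "WMed", 0.012),
        ("WMed", "Sardinia_LBA", 0.02),
        ("WMed", "Iberia_EBA", 0.02),
        # eastern branch
        ("root", "East", 0.02),
        ("East", "IranSide", 0.015),
        ("IranSide", "CHG", 0.03),
        ("IranSide", "Iran_N", 0.03),
        ("East", "LevSide", 0.015),
        ("LevSide", "Natufian", 0.02),
        ("LevSide", "Levant_N", 0.02),
        ("LevSide", "Levant_MLBA", 0.02),
        # steppe branch
        ("root", "Steppe", 0.02),
        ("Steppe", "EHG", 0.03),
        ("Steppe", "Steppe_MLBA", 0.02),
        # North African branch
        ("root", "Afr", 0.03),
        ("Afr", "Tunisia_N", 0.03),
        ("Afr", "NorthAfrica_IA", 0.03),
    ]
    return PopulationTree.from_edges(edges, proxy_sources=PROXY_SOURCES, right_set=CORE_RIGHTS)


def _default_targets() -> list[dict]:
    mixtures = [
        {"Sicily_EMBA": 1.0},
        {"Greece_BA": 0.8, "NorthAfrica_IA": 0.2},
        {"Sicily_EMBA": 0.6, "NorthAfrica_IA": 0.4},
        {"Greece_BA": 0.5, "Levant_MLBA": 0.5},
        {"Levant_MLBA": 1.0},
        {"Sicily_EMBA": 0.7, "Iberia_EBA": 0.3},
    ]
    targets = []
    for s, site in enumerate(("SiteA", "SiteB")):
        for k, weights in enumerate(mixtures):
            targets.append({"id": f"{site}_T{k}", "site": site, "weights": dict(weights)})
    return targets


@dataclass
class PipelineConfig:
    """All thresholds, sizes, and scheme definitions for one run.

    The coverage and diversity gates default to the standard analysis
    values; the synthetic-cohort sizes are deliberately desk-scale.
    """

    n_snps: int = 4000
    n_per_group: int = 12
    missing_rate: float = 0.10
    n_blocks: int = 60
    anchor: str = "El_Miron"
    min_snps: int = 500                # projection gate, scaled to n_snps
    validity_alpha: float = 0.05
    ibd_significance_cm: float = 16.0
    roh_close_kin_cm: float = 50.0
    roh_second_degree_cm: float = 350.0
    diversity_min_individuals: int = 5
    diversity_min_males: int = 5
    pca_components: int = 2
    use_all_snps: bool = True
    targets: list[dict] = field(default_factory=_default_targets)
    haplogroup_spectra: dict = field(
        default_factory=lambda: {
            "SiteA": {"E1b1": 0.3, "R1b1": 0.2, "J2a1": 0.2, "G2a2": 0.2, "J1a2": 0.1},
            "SiteB": {"E1b1": 0.4, "R1b1": 0.3, "J2a1": 0.3},
        }
    )
    haplogroup_counts: dict = field(default_factory=lambda: {"SiteA": 8, "SiteB": 8})

    def validate(self) -> None:
        if self.anchor not in CORE_RIGHTS or CORE_RIGHTS[0] != self.anchor:
            raise PipelineConfigError(
                f"anchor {self.anchor!r} must be the first core right population"
            )
        positive = {
            "n_snps": self.n_snps,
            "n_per_group": self.n_per_group,
            "n_blocks": self.n_blocks,
            "validity_alpha": self.validity_alpha,
            "ibd_significance_cm": self.ibd_significance_cm,
            "roh_close_kin_cm": self.roh_close_kin_cm,
            "roh_second_degree_cm": self.roh_second_degree_cm,
            "diversity_min_individuals": self.diversity_min_individuals,
            "diversity_min_males": self.diversity_min_males,
        }
        for name, value in positive.items():
            if value <= 0:
                raise PipelineConfigError(f"{name} must be positive, got {value}")
        for t in self.targets:
            w = t.get("weights", {})
            unknown = set(w) - set(PROXY_SOURCES)
            if unknown:
                raise PipelineConfigError(f"target {t.get('id')}: unknown sources {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + 7919 * (k + 1)) % (2**31 - 1))


def run_pipeline(
    config: PipelineConfig,
    seed: int,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested stages in order; returns the summary dict.

    Stage outputs land under ``outdir``; any failure aborts with a
    stage-tagged error, preserving outputs of completed stages.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {"config": config, "seed": seed, "outdir": outdir}
    summary: dict = {
        "version": __version__,
        "seed": seed,
        "thresholds": {
            "min_snps": config.min_snps,
            "validity_alpha": config.validity_alpha,
            "ibd_significance_cm": config.ibd_significance_cm,
            "roh_close_kin_cm": config.roh_close_kin_cm,
            "roh_second_degree_cm": config.roh_second_degree_cm,
        },
        "stages": {},
    }
    runners = {
        "simulate": _stage_simulate,
        "qpadm": _stage_qpadm,
        "models": _stage_models,
        "pca": _stage_pca,
        "relatedness": _stage_relatedness,
        "diversity": _stage_diversity,
        "report": _stage_report,
    }
    for k, name in enumerate(STAGES):
        if name not in stages:
            continue
        t0 = time.time()
        log.info("stage %s starting", name)
        try:
            summary["stages"][name] = runners[name](state, summary)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs", name, time.time() - t0)
    return summary


def _load_table(state: dict) -> GenotypeTable:
    if "table" not in state:
        state["table"] = read_eigenstrat(state["outdir"] / "cohort")
    return state["table"]


def _stage_simulate(state: dict, summary: dict) -> dict:
    cfg: PipelineConfig = state["config"]
    seed = _stage_seed(state["seed"], 0)
    tree = default_tree()
    leaves = [n for n in tree.parents if n in PROXY_SOURCES or n in CORE_RIGHTS]
    freqs = draw_frequencies(tree, cfg.n_snps, seed)
    snps = make_snp_table(cfg.n_snps)
    specs = [AdmixtureSpec(t["id"], t["weights"]) for t in cfg.targets]
    table = make_cohort(
        {k: freqs[k] for k in leaves},
        {k: cfg.n_per_group for k in leaves},
        snps,
        missing_rate=cfg.missing_rate,
        seed=seed + 1,
        admixed=specs,
    )
    site_of = {t["id"]: t.get("site", "unknown") for t in cfg.targets}
    table.individuals["site"] = [site_of.get(i, "reference") for i in table.individuals["individual_id"]]
    write_eigenstrat(table, state["outdir"] / "cohort")
    pd.DataFrame(cfg.targets).to_json(state["outdir"] / "targets.json", orient="records")
    state["table"] = table
    state["freqs"] = freqs
    return {"n_snps": cfg.n_snps, "n_individuals": int(table.n_individuals)}


def _stage_qpadm(state: dict, summary: dict) -> dict:
    cfg: PipelineConfig = state["config"]
    table = _load_table(state)
    blocks = BlockScheme.contiguous(table.snps, n_blocks=cfg.n_blocks)
    engine = F4Engine(table, blocks)
    schemes = default_schemes()
    fits_by_target: dict[str, dict[str, list]] = {}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in cfg.targets:
            tid = t["id"]
            fits_by_target[tid] = {}
            for name in ("western", "eastern"):
                scheme = schemes[name]
                fits = []
                for lefts, rights in enumerate_models(scheme):
                    fit = qpadm_fit(
                        table, tid, list(lefts), list(rights), blocks,
                        use_all_snps=cfg.use_all_snps,
                        validity_alpha=cfg.validity_alpha,
                        scheme=name, engine=engine,
                    )
                    fits.append(fit)
                    rows.append(
                        (tid, name, "+".join(lefts),
                         ";".join(f"{s}:{w:.4f}" for s, w in zip(fit.left_set, fit.weights)),
                         fit.chi_square, fit.dof, fit.p_value, fit.feasible, fit.valid)
                    )
                fits_by_target[tid][name] = fits
    long = pd.DataFrame(
        rows,
        columns=["individual", "scheme", "left_set", "weights", "chi_square", "dof", "p_value", "feasible", "valid"],
    )
    long.to_csv(state["outdir"] / "qpadm_fits.tsv", sep="\t", index=False, float_format="%.6g")
    state["fits_by_target"] = fits_by_target
    return {"n_fits": len(rows), "n_valid": int(long["valid"].sum())}


def _stage_models(state: dict, summary: dict) -> dict:
    cfg: PipelineConfig = state["config"]
    reports = {}
    for tid, fits in state["fits_by_target"].items():
        reports[tid] = build_report(tid, fits, alpha=cfg.validity_alpha)
    payload = {tid: r.to_dict() for tid, r in reports.items()}
    with open(state["outdir"] / "model_reports.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    state["model_reports"] = reports
    n_rep = sum(r.representative is not None for r in reports.values())
    return {"n_individuals": len(reports), "n_with_representative": n_rep}


def _stage_pca(state: dict, summary: dict) -> dict:
    cfg: PipelineConfig = state["config"]
    table = _load_table(state)
    seed = _stage_seed(state["seed"], 3)
    # reference panel: fresh low-missingness diploid individuals from the leaves
    tree = default_tree()
    freqs = state.get("freqs") or draw_frequencies(tree, cfg.n_snps, _stage_seed(state["seed"], 0))
    rng = np.random.default_rng(seed)
    ref_pops = ["Sicily_EMBA", "Greece_BA", "NorthAfrica_IA", "Levant_MLBA", "Iberia_EBA"]
    cols, ids, groups = [], [], []
    for pop in ref_pops:
        dip = rng.binomial(2, freqs[pop][:, None], size=(cfg.n_snps, 20)).astype(np.int8)
        cols.append(dip)
        ids += [f"ref_{pop}_{i}" for i in range(20)]
        groups += [pop] * 20
    reference = GenotypeTable(
        snps=table.snps,
        individuals=pd.DataFrame({"individual_id": ids, "sex": "unknown", "group_label": groups}),
        calls=np.hstack(cols),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_pca(reference, cfg.pca_components, loo_size=20, seed=seed)
    model.save(state["outdir"] / "pca_model")
    ref_proj = project_reference(model, reference)
    by_group: dict[str, list] = {}
    for p, g in zip(ref_proj, groups):
        by_group.setdefault(g, []).append(p)
    rows = []
    projections = {}
    for t in cfg.targets:
        tid = t["id"]
        try:
            proj = project(model, table, tid, min_snps=cfg.min_snps)
        except ValueError as exc:
            log.warning("skipping projection of %s: %s", tid, exc)
            continue
        cline = cline_fraction(proj, by_group["Sicily_EMBA"], by_group["NorthAfrica_IA"])
        projections[tid] = proj
        rows.append((tid, t.get("site", ""), *proj.coordinates[:2], cline.fraction_b))
    proj_df = pd.DataFrame(rows, columns=["iid", "site", "PC1", "PC2", "cline_north_african"])
    proj_df.to_csv(state["outdir"] / "projections.tsv", sep="\t", index=False, float_format="%.6g")
    state["projections"] = projections
    state["projection_df"] = proj_df
    return {"n_projected": len(rows)}


def _stage_relatedness(state: dict, summary: dict) -> dict:
    cfg: PipelineConfig = state["config"]
    table = _load_table(state)
    seed = _stage_seed(state["seed"], 4)
    blocks = BlockScheme.contiguous(table.snps, n_blocks=cfg.n_blocks)
    # mismatch/kinship among the first site's targets, baseline from reference pairs
    tids = [t["id"] for t in cfg.targets]
    site1 = [t["id"] for t in cfg.targets if t.get("site") == cfg.targets[0].get("site")]
    ref_ids = [f"Sicily_EMBA_{i}" for i in range(min(4, cfg.n_per_group))]
    base_pairs = [(a, b) for i, a in enumerate(ref_ids) for b in ref_ids[i + 1:]]
    b = baseline_b(table, base_pairs, blocks)
    kin_rows = []
    for i, a in enumerate(site1):
        for c in site1[i + 1:]:
            mm = pairwise_mismatch(table, a, c, blocks)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kin = kinship_r(mm.x, b)
            kin_rows.append((a, c, mm.x, mm.ci95[0], mm.ci95[1], mm.n_overlap, kin.r))
    kin_df = pd.DataFrame(
        kin_rows, columns=["iid1", "iid2", "mismatch", "ci_lo", "ci_hi", "n_overlap", "kinship_r"]
    )
    kin_df.to_csv(state["outdir"] / "kinship.tsv", sep="\t", index=False, float_format="%.6g")

    # pedigree ground truth -> IBD classification, ROH summaries, dating
    sib = simulate_pedigree(sibling_pedigree(), seed)
    cousin = simulate_pedigree(cousin_offspring_pedigree(1), seed + 1)
    segs = sib.true_segments()
    segs.to_tsv(state["outdir"] / "ibd_segments.tsv", state["outdir"] / "roh_segments.tsv")
    ibd_rows = []
    for (a, c), grp in segs.ibd.groupby(["iid1", "iid2"]):
        s = IbdSummary.from_segments(a, c, grp["length_cM"].to_numpy())
        cls = classify_pair(s)
        age = segment_age(cfg.ibd_significance_cm) if s.n_over(cfg.ibd_significance_cm) else None
        ibd_rows.append(
            (a, c, s.n_over_12cm, s.sum_over_12cm, cls, age.median if age else "", age.q95 if age else "")
        )
    ibd_df = pd.DataFrame(
        ibd_rows,
        columns=["iid1", "iid2", "n_over_12cM", "sum_over_12cM", "class", "age_median_gen", "age_q95_gen"],
    )
    ibd_df.to_csv(state["outdir"] / "ibd_classification.tsv", sep="\t", index=False, float_format="%.6g")
    roh_segs = cousin.true_segments(pairs=[])
    offspring_roh = roh_segs.roh[roh_segs.roh["iid"] == "O"]
    roh_sum = roh_summarize("O", offspring_roh["length_cM"].to_numpy())
    with open(state["outdir"] / "roh_summary.json", "w") as fh:
        json.dump(
            {
                "individual": "O",
                "bins_cM": roh_sum.bin_totals_cm,
                "sum_over_20cM": roh_sum.sum_over_20cm,
                "parental_class": roh_sum.parental_class,
            },
            fh, indent=1, sort_keys=True,
        )
    return {
        "baseline_b": round(b, 6),
        "n_kinship_pairs": len(kin_rows),
        "n_classified_pairs": len(ibd_rows),
        "cousin_offspring_roh_cM": round(roh_sum.sum_over_20cm, 2),
        "cousin_offspring_class": roh_sum.parental_class,
    }


def _stage_diversity(state: dict, summary: dict) -> dict:
    cfg: PipelineConfig = state["config"]
    seed = _stage_seed(state["seed"], 5)
    out: dict = {}
    rows = []
    if "projections" in state:
        by_site: dict[str, list] = {}
        for t in cfg.targets:
            if t["id"] in state["projections"]:
                by_site.setdefault(t.get("site", "unknown"), []).append(state["projections"][t["id"]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for site, projs in sorted(by_site.items()):
                d = site_diversity(projs, min_individuals=cfg.diversity_min_individuals)
                if d is not None:
                    rows.append((site, len(projs), d))
    pc_df = pd.DataFrame(rows, columns=["site", "n", "pc_diversity"])
    sites = sorted(cfg.haplogroup_spectra)
    hap_table = assign_haplogroups(sites, cfg.haplogroup_spectra, cfg.haplogroup_counts, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hap_df = site_haplogroup_diversity(
            hap_table, min_males=cfg.diversity_min_males, snp_gate=None
        )
    pc_df.to_csv(state["outdir"] / "pc_diversity.tsv", sep="\t", index=False, float_format="%.6g")
    hap_df.to_csv(state["outdir"] / "y_diversity.tsv", sep="\t", index=False, float_format="%.6g")
    out["pc_diversity"] = {
        site: round(val, 4) for site, val in zip(pc_df["site"], pc_df["pc_diversity"])
    }
    out["y_diversity"] = {
        site: round(val, 4) for site, val in zip(hap_df["site"], hap_df["index"])
    }
    return out


def _stage_report(state: dict, summary: dict) -> dict:
    path = state["outdir"] / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {"path": str(path)}
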