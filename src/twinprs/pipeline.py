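"""End-to-end study orchestration: simulate -> twin models -> PRS.

A single YAML config drives all stages; one global seed is split into
named substreams per stage so partial re-runs reproduce bit-identically.
Each run emits TSV tables shaped like the standard reporting layout of a
disorder-trait twin/PRS study (saturated correlations per pairing, model
fits and selection, concordances, PRS associations at every threshold with
and without diagnosed individuals) plus a JSON run manifest with config
hash and per-stage file digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import prs as tprs
from . import twin as ttwin
from . import simulate as tsim
from .types import (
    ZYGOSITY_GROUPS,
    BivariateTwinSpec,
    ClumpSpec,
    EtiologicCorrelations,
    PolygenicSpec,
    ThresholdSet,
    VarianceComponents,
)

logger = logging.getLogger("twinprs")

_REDUCTION_CHAIN = {
    "ACE": ["AE", "CE", "E"],
    "ADE": ["AE", "E"],
    "AE": ["E"],
    "CE": ["E"],
    "E": [],
}


@dataclass
class AnalysisConfig:
    """Validated study configuration (YAML-serializable)."""

    seed: int = 0
    pairings: list[dict] = field(default_factory=list)
    thresholds: list[float] = field(
        default_factory=lambda: list(tprs.DEFAULT_THRESHOLDS))
    primary_threshold: float = tprs.PRIMARY_THRESHOLD
    clump: ClumpSpec = field(default_factory=ClumpSpec)
    n_pcs: int = 10
    fdr_level: float = 0.05
    outcomes: list[dict] = field(default_factory=list)
    simulate: dict = field(default_factory=dict)

    def validate(self) -> "AnalysisConfig":
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        thr = list(self.thresholds)
        if thr != sorted(thr):
            raise ValueError("thresholds must be sorted ascending")
        if not thr:
            raise ValueError("threshold list must not be empty")
        if self.primary_threshold not in thr:
            raise ValueError("primary threshold must be in the threshold list")
        self.clump.validate()
        for pairing in self.pairings:
            fam = pairing.get("family", "ACE").removesuffix("-s")
            if fam not in _REDUCTION_CHAIN:
                raise ValueError(f"unknown model family {fam!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        clump = ClumpSpec(**raw.pop("clump", {}))
        cfg = cls(clump=clump, **{k: v for k, v in raw.items()
                                  if k in cls.__dataclass_fields__})
        return cfg.validate()

    def to_yaml(self, path) -> None:
        raw = {
            "seed": self.seed, "pairings": self.pairings,
            "thresholds": [float(t) for t in self.thresholds],
            "primary_threshold": float(self.primary_threshold),
            "clump": {"r2": self.clump.r2,
                      "window_kb": self.clump.window_kb,
                      "p_ceiling": self.clump.p_ceiling},
            "n_pcs": self.n_pcs, "fdr_level": self.fdr_level,
            "outcomes": self.outcomes, "simulate": self.simulate,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in
             ("seed", "pairings", "thresholds", "primary_threshold",
              "n_pcs", "fdr_level", "outcomes", "simulate")},
            sort_keys=True, default=str).encode()
        blob += repr((self.clump.r2, self.clump.window_kb,
                      self.clump.p_ceiling)).encode()
        return hashlib.sha256(blob).hexdigest()


def twin_spec_from_config(cfg: AnalysisConfig) -> BivariateTwinSpec:
    raw = dict(cfg.simulate.get("twin", {}))
    prev = raw.pop("prevalence", 0.01)
    prev_f = raw.pop("prevalence_f", None)
    spec = BivariateTwinSpec(
        trait=VarianceComponents(**raw.pop("trait", {"a2": 0.6, "e2": 0.4})),
        liability=VarianceComponents(
            **raw.pop("liability", {"a2": 0.8, "e2": 0.2})),
        corr=EtiologicCorrelations(**raw.pop("corr", {"rA": 0.5, "rE": 0.3})),
        thresholds=ThresholdSet.from_prevalence(prev, prev_f),
        seed=cfg.seed,
        **raw,
    )
    return spec.validate()


def polygenic_spec_from_config(cfg: AnalysisConfig) -> PolygenicSpec:
    raw = dict(cfg.simulate.get("polygenic", {}))
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    return PolygenicSpec(seed=cfg.seed, **raw).validate()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_study(cfg: AnalysisConfig, out_dir) -> dict[str, Path]:
    """Generate the synthetic cohort (phenotypes, genotypes, sumstats)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tspec = twin_spec_from_config(cfg)
    table = tsim.simulate_twin_pairs(tspec)
    pspec = polygenic_spec_from_config(cfg)
    geno, meta = tsim.simulate_genotypes(pspec, table)
    effects = tsim.draw_causal_effects(pspec)
    sumstats = tsim.simulate_discovery_sumstats(
        pspec, geno.variants, meta["maf"], effects)
    outcomes = tsim.attach_genetic_phenotype(geno, effects, pspec,
                                             subpop=meta["subpop"])
    df = table.df.copy()
    iid = df["pair_id"].astype(str) + "_" + df["twin_order"].astype(str)
    for col in ("score_outcome", "true_score"):
        df[col] = outcomes[col].reindex(iid).to_numpy()
    df["score_dx"] = outcomes["score_dx"].reindex(iid).to_numpy()
    full = tio.PhenotypeTable(
        df=df,
        measures=table.measures + ["score_outcome", "true_score"],
        diagnoses=table.diagnoses + ["score_dx"])
    paths = {
        "phenotypes": out_dir / "phenotypes.tsv",
        "sumstats": out_dir / "sumstats.tsv",
        "genotypes": out_dir / "genotypes",
    }
    tio.write_phenotypes(full, paths["phenotypes"])
    tio.write_summary_stats(sumstats, paths["sumstats"])
    tio.write_plink(geno, paths["genotypes"])
    return paths


def run_twin_study(cfg: AnalysisConfig,
                   table: tio.PhenotypeTable) -> dict[str, pd.DataFrame]:
    """Saturated correlations, structural fits, selection and concordances."""
    cfg.validate()
    if not cfg.pairings:
        raise ValueError("config defines no trait-diagnosis pairings")
    corr_rows, fit_rows, sel_rows, conc_rows = [], [], [], []
    for pairing in cfg.pairings:
        trait = pairing["trait"]
        dx = pairing["diagnosis"]
        family = pairing.get("family", "ACE")
        label = f"{dx}~{trait}"
        sat = ttwin.fit_saturated(table, trait, dx)
        row = sat.to_frame()
        row.insert(0, "pairing", label)
        corr_rows.append(row)

        base = family.removesuffix("-s")
        sib = family.endswith("-s")
        full = ttwin.BivariateTwinModel(
            family=base, sibling_interaction=sib).fit(table, trait, dx)
        reduced = []
        red_labels = [family]
        for fam in _REDUCTION_CHAIN[base]:
            reduced.append(ttwin.BivariateTwinModel(family=fam).fit(
                table, trait, dx))
            red_labels.append(fam)
        sel = ttwin.select_model(full, reduced, labels=red_labels)
        sel.insert(0, "pairing", label)
        sel_rows.append(sel)
        favored_idx = int(sel.index[sel["favored"]][0])
        favored = ([full] + reduced)[favored_idx]
        frow = favored.to_frame()
        frow.insert(0, "pairing", label)
        fit_rows.append(frow)

        conc = ttwin.probandwise_concordance(table, dx)
        conc.insert(0, "pairing", label)
        conc_rows.append(conc)
    return {
        "twin_correlations": pd.concat(corr_rows, ignore_index=True),
        "twin_fits": pd.concat(fit_rows, ignore_index=True),
        "model_selection": pd.concat(sel_rows, ignore_index=True),
        "concordances": pd.concat(conc_rows, ignore_index=True),
    }


def _individual_frame(table: tio.PhenotypeTable) -> pd.DataFrame:
    df = table.df.copy()
    df["individual_id"] = (df["pair_id"].astype(str) + "_"
                           + df["twin_order"].astype(str))
    df["sex_code"] = (df["sex"] == "F").astype(float)
    return df.set_index("individual_id")


def mz_cotwin_ids(table: tio.PhenotypeTable) -> set[str]:
    """Second-twin ids of MZ pairs (genotype duplicates to drop from PCA)."""
    df = table.df
    mz = df[df["zygosity"].str.startswith("MZ") & (df["twin_order"] == 2)]
    return set(mz["pair_id"].astype(str) + "_2")


def run_prs_study(cfg: AnalysisConfig, geno: tio.GenotypeData,
                  sumstats: pd.DataFrame,
                  table: tio.PhenotypeTable) -> dict[str, pd.DataFrame]:
    """PRS scoring and GEE associations at every threshold, with FDR.

    For each configured outcome the association runs at every threshold on
    the full sample, and again at the primary threshold after excluding
    individuals carrying the relevant diagnosis (``exclude_dx``).  FDR is
    applied jointly to the primary-threshold full-sample family, and
    separately within each non-primary threshold.
    """
    cfg.validate()
    if not cfg.outcomes:
        raise ValueError("config defines no PRS outcomes")
    profile = tprs.PrsScorer(thresholds=cfg.thresholds,
                             clump=cfg.clump).fit_transform(geno, sumstats)
    pcs = tprs.pca_covariates(geno, k=cfg.n_pcs,
                              exclude=mz_cotwin_ids(table))
    ind = _individual_frame(table)
    ind = ind.loc[[i for i in geno.ids if i in ind.index]]
    covar_cols = list(pcs.columns) + ["sex_code"]
    if ind["age_cohort"].nunique() > 1:
        ind["age_num"] = pd.to_numeric(ind["age_cohort"])
        covar_cols.append("age_num")
    data = ind.join(pcs, how="inner")

    rows = []
    for spec in cfg.outcomes:
        name = spec["name"]
        family = spec.get("family", "linear")
        exclude_dx = spec.get("exclude_dx")
        for thr in cfg.thresholds:
            z = profile.z(thr).reindex(data.index)
            res = tprs.gee_associate(
                data[name], z, data[covar_cols],
                clusters=data["pair_id"], family=family,
                outcome_name=name, threshold=thr)
            rows.append(res.to_dict())
            if thr == cfg.primary_threshold and exclude_dx:
                sub = tprs.exclude_diagnosed(data, exclude_dx)
                res_x = tprs.gee_associate(
                    sub[name], profile.z(thr).reindex(sub.index),
                    sub[covar_cols], clusters=sub["pair_id"], family=family,
                    outcome_name=name, threshold=thr, excluded=True)
                rows.append(res_x.to_dict())
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    primary = (out["threshold"] == cfg.primary_threshold) & ~out["excluded"]
    out.loc[primary, "p_fdr"] = tprs.fdr_adjust(out.loc[primary, "p"])
    for thr in cfg.thresholds:
        if thr == cfg.primary_threshold:
            continue
        fam_mask = (out["threshold"] == thr) & ~out["excluded"]
        out.loc[fam_mask, "p_fdr"] = tprs.fdr_adjust(out.loc[fam_mask, "p"])
    assoc = out[out["threshold"] == cfg.primary_threshold].reset_index(drop=True)
    return {"prs_associations": assoc, "prs_sensitivity": out}


# ---------------------------------------------------------------------------
# manifest and entry points
# ---------------------------------------------------------------------------

def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: AnalysisConfig, out_dir, stage_times: dict,
                   files: list[Path]) -> Path:
    from . import __version__

    manifest = {
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "package_version": __version__,
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "files": {str(Path(p).name): _digest_file(Path(p)) for p in files},
    }
    path = Path(out_dir) / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def run_all(cfg: AnalysisConfig, out_dir) -> dict:
    """simulate -> twin models -> PRS, with results and manifest on disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    times = {}
    t0 = time.perf_counter()
    paths = simulate_study(cfg, out_dir / "data")
    times["simulate"] = time.perf_counter() - t0

    table = tio.read_phenotypes(paths["phenotypes"])
    written: list[Path] = list(paths.values())
    written.remove(paths["genotypes"])

    tables = {}
    if cfg.pairings:
        t0 = time.perf_counter()
        tables.update(run_twin_study(cfg, table))
        times["twin"] = time.perf_counter() - t0
    if cfg.outcomes:
        t0 = time.perf_counter()
        geno = tio.read_plink(paths["genotypes"])
        sumstats = tio.read_summary_stats(paths["sumstats"])
        tables.update(run_prs_study(cfg, geno, sumstats, table))
        times["prs"] = time.perf_counter() - t0
    written += tio.write_results(tables, out_dir / "results")
    manifest = write_manifest(cfg, out_dir, times, written)
    return {"tables": tables, "manifest": manifest, "paths": paths}


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Small self-consistent dataset: 500 pairs, 200 variants, one GWAS."""
    cfg = AnalysisConfig(
        seed=seed,
        simulate={
            "twin": {
                "trait": {"a2": 0.6, "e2": 0.4},
                "liability": {"a2": 0.8, "e2": 0.2},
                "corr": {"rA": 0.5, "rE": 0.3},
                "prevalence": 0.05,
                "n_pairs": {g: 100 for g in ZYGOSITY_GROUPS},
            },
            "polygenic": {"m_variants": 200, "n_causal": 20,
                          "n_discovery": 20_000, "h2_score": 0.1},
        },
    )
    return simulate_study(cfg, out_dir)
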