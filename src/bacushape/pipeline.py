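"""End-to-end analysis orchestration.

Runs the full workflow — specimen shapes → complexity table → phylogenetic
signal → regime model selection across stochastic maps → MCMC regressions →
coevolution Bayes factors → regional repeated-measures ANOVA — from a single
config, with per-stage outputs, recorded seeds, and a species-exclusion flag
for sensitivity reruns.  Two profiles exist: the *synthetic* profile
generates specimens and comparative data from the simulators, exercising
every stage; the *reproduction* profile ingests a ready-made trait table
(CSV) plus Newick trees and skips the shape stage.

Missing trait values drop species per-analysis (complete cases for each
regression separately), so different analyses can have different n — signal
uses every species with a complexity value even when testes mass is NA.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha_complexity, comparative_stats, phylo_models, shape_io
from .comparative_stats import MCMCSettings, prune_to
from .synthetic_shapes import ShapeSpec, make_baculum
from .trait_sim import (simulate_discrete_history, simulate_trait,
                        simulate_yule_tree)
from .trees import Phylogeny

__all__ = ["AnalysisConfig", "run_analysis", "ingest_trait_table",
           "synthetic_dataset"]

TESTES_DENSITY_G_PER_CM3 = 0.81
SOCIAL_STATES = ["GL", "S", "SM"]


@dataclass
class AnalysisConfig:
    """Everything one run needs; every output records the seeds used."""

    seed: int = 0
    outdir: str | None = None
    profile: str = "synthetic"              # synthetic | reproduction
    # synthetic profile
    n_species: int = 12
    n_shape_points: int = 8000
    n_maps: int = 5
    # reproduction profile
    trait_table: str | None = None
    tree_path: str | None = None
    tree_block_path: str | None = None
    # shared
    exclude_species: list[str] = field(default_factory=list)
    mcmc: str = "fast"                      # fast | default | full
    regions: int = 3

    def settings(self) -> MCMCSettings:
        return {"fast": MCMCSettings.fast(), "default": MCMCSettings(),
                "full": MCMCSettings.full_scale()}[self.mcmc]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml
        return cls(**yaml.safe_load(Path(path).read_text()))


def ingest_trait_table(path: str | Path) -> pd.DataFrame:
    """Read an S1-style trait CSV, converting testes volume to mass.

    Columns: species, complexity, baculum_length_mm, body_mass_kg,
    testes_mass_g (or testes_volume_cm3), social_system {GL,S,SM},
    ovulation {spontaneous,induced}, intromission_duration; "NA" = missing.
    Rows whose testes mass was derived from a volume (density 0.81 g/cm³)
    are flagged in ``testes_mass_from_volume``.
    """
    df = pd.read_csv(path, na_values=["NA"])
    df = df.set_index("species")
    df["testes_mass_from_volume"] = False
    if "testes_volume_cm3" in df.columns:
        need = df["testes_mass_g"].isna() & df["testes_volume_cm3"].notna() \
            if "testes_mass_g" in df.columns else df["testes_volume_cm3"].notna()
        if "testes_mass_g" not in df.columns:
            df["testes_mass_g"] = np.nan
        df.loc[need, "testes_mass_g"] = \
            df.loc[need, "testes_volume_cm3"] * TESTES_DENSITY_G_PER_CM3
        df.loc[need, "testes_mass_from_volume"] = True
    return df


# ---------------------------------------------------------------------------
# synthetic dataset generation

_REGIME_SHAPES = {
    # group-living: plain rod; solitary: grooved; social monogamy: groove+hook
    0: dict(),
    1: dict(groove_depth=0.45),
    2: dict(groove_depth=0.45, hook_angle=240.0),
}


def synthetic_dataset(cfg: AnalysisConfig) -> dict:
    """Simulate a full comparative dataset with 3D specimens per tip.

    Regimes (social systems) evolve on a Yule tree; each species' shape spec
    inherits its regime's feature set (plus mild curvature), so measured
    complexity genuinely tracks the regime history.  Covariates (body mass,
    testes mass with some NAs, intromission duration, ovulation) are
    simulated Brownian/threshold traits.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_yule_tree(cfg.n_species, seed=int(rng.integers(2**31)))
    Q = 1.0 * (np.full((3, 3), 0.5) - 1.5 * np.eye(3)) / 1.0
    painted = simulate_discrete_history(tree, Q,
                                        seed=int(rng.integers(2**31)))
    while len(set(painted.tip_states())) < 3:
        painted = simulate_discrete_history(tree, Q,
                                            seed=int(rng.integers(2**31)))
    states = painted.tip_states()
    shapes = {}
    for i, sp in enumerate(tree.tip_labels):
        kw = dict(_REGIME_SHAPES[int(states[i])])
        shapes[sp] = ShapeSpec(kind="baculum", curvature_angle=0.3,
                               n=cfg.n_shape_points,
                               seed=int(rng.integers(2**31)), **kw)
    body = simulate_trait(painted, "BM1", dict(root=1.0, sigma2=0.3),
                          seed=int(rng.integers(2**31)))
    testes = 0.8 * body + simulate_trait(
        painted, "BM1", dict(root=0.0, sigma2=0.1),
        seed=int(rng.integers(2**31)))
    intro = simulate_trait(painted, "BM1", dict(root=1.0, sigma2=0.2),
                           seed=int(rng.integers(2**31)))
    ovul = (simulate_trait(painted, "BM1", dict(root=0.0, sigma2=1.0),
                           seed=int(rng.integers(2**31))) > 0).astype(int)
    traits = pd.DataFrame({
        "body_mass_kg": 10 ** body,
        "testes_mass_g": 10 ** testes,
        "intromission_duration": 10 ** intro,
        "ovulation": np.where(ovul, "induced", "spontaneous"),
        "social_system": [SOCIAL_STATES[int(s)] for s in states],
    }, index=tree.tip_labels)
    # a couple of NAs, as in real literature-compiled testes data
    na_idx = rng.choice(cfg.n_species, size=max(1, cfg.n_species // 6),
                        replace=False)
    traits.iloc[na_idx, traits.columns.get_loc("testes_mass_g")] = np.nan
    return {"tree": tree, "painted": painted, "shapes": shapes,
            "traits": traits}


def _complexity_table(shapes: dict[str, ShapeSpec], regions: int) -> pd.DataFrame:
    rows = {}
    for sp, spec in shapes.items():
        # smoke-profile pitch: ~0.3% reference-volume error, far below the
        # sampling noise of these small clouds
        pc = shape_io.normalize(make_baculum(spec,
                                             pitch=spec.shaft_radius / 15))
        res = alpha_complexity.regional_complexity(pc, n_regions=regions)
        row = {"complexity": res.complexity,
               "alpha_star": res.alpha_star,
               "at_ceiling": res.at_ceiling,
               "baculum_length_mm": spec.shaft_length * 40.0}
        for lab, r in res.regions.items():
            row[f"complexity_{lab}"] = r.complexity
        rows[sp] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    return df


# ---------------------------------------------------------------------------
# stages

def _stage_signal(tree: Phylogeny, table: pd.DataFrame) -> dict:
    avail = table["complexity"].dropna()
    sub = prune_to(tree, list(avail.index)) if len(avail) < tree.n_tips \
        else tree
    fit = phylo_models.pagel_lambda(sub, np.log10(avail.reindex(sub.tip_labels)))
    anc = phylo_models.ancestral_states_bm(
        sub, np.log10(avail.reindex(sub.tip_labels)))
    return {"n": int(len(avail)), **fit.to_dict(),
            "root_state": float(anc.iloc[0])}


def _stage_regimes(tree: Phylogeny, table: pd.DataFrame,
                   traits: pd.DataFrame, n_maps: int, seed: int) -> dict:
    y = np.log10(table["complexity"].reindex(tree.tip_labels))
    social = traits["social_system"].reindex(tree.tip_labels)
    mk = phylo_models.fit_mk(tree, social, "SYM")
    maps = phylo_models.sample_stochastic_maps(tree, social, mk,
                                               n_maps=n_maps, seed=seed)
    fits = []
    for i, m in enumerate(maps):
        per_map = {}
        for name in ("BM1", "BMS", "OU1", "OUM", "OUMV"):
            try:
                per_map[name] = phylo_models.fit_trait_model(m, y, name,
                                                             seed=seed + i)
            except ValueError:
                # a sampled map can miss a regime a multi-regime model needs
                continue
        fits.append(per_map)
    sel = phylo_models.model_select(fits)
    return {"mk_loglik": mk.loglik, "n_maps": n_maps,
            "selection": sel.table.to_dict(orient="records"),
            "best_tally": sel.best_tally,
            "frac_second_within_2": sel.frac_second_within_2}


def _stage_pgls(tree: Phylogeny, table: pd.DataFrame, traits: pd.DataFrame,
                settings: MCMCSettings, seed: int) -> dict:
    out = {}
    for resp_name, col in (("baculum_length", "baculum_length_mm"),
                           ("baculum_complexity", "complexity")):
        df = pd.DataFrame({
            "y": np.log10(table[col]),
            "testes_mass": np.log10(traits["testes_mass_g"]),
            "body_mass": np.log10(traits["body_mass_kg"]),
        }).dropna()
        sub = prune_to(tree, list(df.index))
        df = df.reindex(sub.tip_labels)
        post = comparative_stats.pgls_mcmc(
            sub, df["y"], df[["testes_mass", "body_mass"]],
            settings=settings, seed=seed, compute_logml=False)
        out[resp_name] = {
            "n": post.n, "lambda": float(post.mean["lambda"]),
            "intercept": float(post.mean["intercept"]),
            "r2": post.r2,
            "slopes": post.summary().to_dict(orient="records"),
        }
        seed += 11
    return out


def _stage_coevolution(tree: Phylogeny, table: pd.DataFrame,
                       traits: pd.DataFrame, settings: MCMCSettings,
                       seed: int) -> dict:
    norm_testes = np.log10(traits["testes_mass_g"] / traits["body_mass_kg"])
    out = {}
    for name, col in (("length_vs_testes", "baculum_length_mm"),
                      ("complexity_vs_testes", "complexity")):
        res = comparative_stats.coevolution_test(
            tree, np.log10(table[col]), norm_testes,
            settings=settings, seed=seed)
        out[name] = {"logbf": res.logbf, "category": res.category,
                     "logml_dependent": res.logml_dependent,
                     "logml_independent": res.logml_independent}
        seed += 13
    return out


def _stage_regional(tree: Phylogeny, table: pd.DataFrame,
                    traits: pd.DataFrame, settings: MCMCSettings,
                    seed: int) -> dict:
    region_cols = [c for c in table.columns if c.startswith("complexity_")]
    Y = np.log10(table[region_cols].dropna().to_numpy())
    rm = comparative_stats.rm_anova_gg(Y)
    out = {"rm_anova": rm.to_dict(), "region_order": region_cols}
    tipcol = "complexity_distal"
    if tipcol in table.columns:
        for name, pred in (("tip_vs_intromission",
                            np.log10(traits["intromission_duration"])),
                           ("tip_vs_ovulation",
                            (traits["ovulation"] == "induced").astype(float))):
            df = pd.DataFrame({"y": np.log10(table[tipcol]),
                               "x": pred}).dropna()
            if df["x"].nunique() < 2:
                out[name] = {"n": int(df.shape[0]),
                             "skipped": "predictor constant in this subset"}
                continue
            sub = prune_to(tree, list(df.index))
            df = df.reindex(sub.tip_labels)
            post = comparative_stats.pgls_mcmc(
                sub, df["y"], df[["x"]], settings=settings, seed=seed,
                compute_logml=False)
            out[name] = {"n": post.n, "lambda": float(post.mean["lambda"]),
                         "r2": post.r2, "beta": float(post.mean["x"]),
                         "p": post.p_values["x"]}
            seed += 17
    return out


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Execute every stage in order; returns the JSON-serializable report."""
    if cfg.profile == "synthetic":
        data = synthetic_dataset(cfg)
        tree, traits = data["tree"], data["traits"]
        table = _complexity_table(data["shapes"], cfg.regions)
    elif cfg.profile == "reproduction":
        if not cfg.trait_table or not cfg.tree_path:
            raise ValueError("reproduction profile needs trait_table and "
                             "tree_path")
        traits = ingest_trait_table(cfg.trait_table)
        tree = Phylogeny.read(cfg.tree_path)
        missing = sorted(set(traits.index) - set(tree.tip_labels))
        extra_tips = sorted(set(tree.tip_labels) - set(traits.index))
        if missing:
            raise ValueError(f"species not in tree: {missing[:10]}")
        if extra_tips:
            tree = prune_to(tree, list(traits.index))
        table = traits[[c for c in traits.columns
                        if c.startswith("complexity")
                        or c == "baculum_length_mm"]].copy()
    else:
        raise ValueError(f"unknown profile {cfg.profile!r}")

    if cfg.exclude_species:
        keep = [s for s in tree.tip_labels if s not in
                set(cfg.exclude_species)]
        tree = prune_to(tree, keep)
        traits = traits.reindex(keep)
        table = table.reindex(keep)

    settings = cfg.settings()
    rng = np.random.default_rng(cfg.seed + 101)
    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "profile": cfg.profile,
            "config": {k: v for k, v in asdict(cfg).items()},
            "n_species": int(tree.n_tips),
        },
        "complexity_table": table.reset_index().to_dict(orient="records"),
        "signal": _stage_signal(tree, table),
        "regimes": _stage_regimes(tree, table, traits,
                                  n_maps=cfg.n_maps, seed=cfg.seed + 211),
        "pgls": _stage_pgls(tree, table, traits, settings, cfg.seed + 307),
        "coevolution": _stage_coevolution(tree, table, traits, settings,
                                          cfg.seed + 401),
        "regional": _stage_regional(tree, table, traits, settings,
                                    cfg.seed + 503),
    }
    # hash covers the scientific configuration, not output placement
    blob = json.dumps({k: v for k, v in
                       report["provenance"]["config"].items()
                       if k != "outdir"}, sort_keys=True)
    report["provenance"]["config_hash"] = hashlib.sha256(
        blob.encode()).hexdigest()[:16]
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "complexity_table.csv")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not serializable: {type(o)}")
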