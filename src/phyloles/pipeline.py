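"""Full-analysis orchestration and report writing.

Runs the stages in order -- traits, phylogeny, spectrum, trait-evolution
models, PGLS, environment, distance regressions -- against either files
on disk or a synthetic fixture, and writes one delimited file per block
plus a machine-readable JSON summary.  A stage failure marks its block
failed with the diagnostic; later independent stages still run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import evomodels, pgls, spectrum, traits
from .phylo import (
    Alignment,
    DistanceMatrix,
    PhyloCovariance,
    Tree,
    pairwise_tn93,
    parse_newick,
    patristic_distances,
    read_fasta,
    tree_vcv,
    write_distance_matrix,
)
from .simulate import Fixture, FixtureConfig, simulate_fixture
from .traits import ENV_VARIABLES, TRAIT_COLUMNS, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "AnalysisReport",
    "anova_by_group",
    "pass_environment_fits",
    "run_pipeline",
    "significance_stars",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    degenerate: bool = False  # zero within-group variance


def anova_by_group(values, groups, *, log10_first: bool = False) -> AnovaResult:
    """One-way ANOVA of values across groups (optionally log10 first).

    Groups with zero within-group variance everywhere make F unbounded;
    that case is flagged ``degenerate`` with F = inf, p = 0 rather than
    failing silently.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if log10_first:
        if np.any(v <= 0):
            raise ValueError("log10 requested but values are not all positive")
        v = np.log10(v)
    levels = pd.unique(g)
    samples = [v[g == lev] for lev in levels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    within = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples)
    if within == 0:
        means = [s.mean() for s in samples]
        if np.ptp(means) == 0:
            raise ValueError("all values identical; ANOVA undefined")
        return AnovaResult(F=float("inf"), p=0.0, degenerate=True)
    F, p = stats.f_oneway(*samples)
    return AnovaResult(F=float(F), p=float(p))


def significance_stars(p: float) -> str:
    """The printed-table convention: *** <0.001, ** <0.01, * <0.05."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pass_environment_fits(
    pass_scores: pd.Series,
    env: pd.DataFrame,
    table: TraitTable,
    C: PhyloCovariance,
    *,
    mode: str = "fixed-bm",
) -> pd.DataFrame:
    """Per-habit PGLS of PASS on MAT, soil C/N and soil N/P.

    Environment is plot-level: species get the per-elevation mean of
    each variable, joined by elevation label.  The covariance is
    restricted to each habit's species (equivalent to pruning).
    """
    env_means = env.groupby("elevation")[["MAT", "soil_CN", "soil_NP"]].mean()
    elev = table.elevation()
    unjoined = sorted(set(elev.unique()) - set(env_means.index))
    if unjoined:
        raise ValueError(f"species elevations without environment rows: {unjoined}")
    rows = []
    for habit in ("evergreen", "deciduous"):
        labels = [s for s in C.labels if table.habit()[s] == habit]
        if len(labels) < 3:
            continue
        Csub = C.subset(labels)
        y = pass_scores.loc[labels]
        for var in ("MAT", "soil_CN", "soil_NP"):
            x = elev.loc[labels].map(env_means[var])
            if x.nunique() < 2:
                raise ValueError(f"constant predictor {var!r} for {habit} species")
            X = pd.DataFrame(
                {"Intercept": np.ones(len(labels)), var: x.to_numpy(float)},
                index=labels,
            )
            fit = pgls.pgls_fit(y, X, Csub, mode=mode)
            rows.append(
                {
                    "habit": habit,
                    "predictor": var,
                    "slope": float(fit.params[var]),
                    "intercept": float(fit.params["Intercept"]),
                    "p": float(fit.pvalues[var]),
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                    "lambda": fit.lam,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """All result blocks plus provenance; blocks that failed carry the
    diagnostic under ``failures``."""

    spectrum: dict = field(default_factory=dict)
    evolution: dict = field(default_factory=dict)
    pgls: dict = field(default_factory=dict)
    environment: dict = field(default_factory=dict)
    distance: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def summary(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, pd.DataFrame):
                return json.loads(obj.to_json(orient="split"))
            if isinstance(obj, pd.Series):
                return json.loads(obj.to_json())
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return clean(
            {
                "spectrum": self.spectrum,
                "evolution": self.evolution,
                "pgls": self.pgls,
                "environment": self.environment,
                "distance": self.distance,
                "provenance": self.provenance,
                "failures": self.failures,
            }
        )


def _fingerprint(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_pipeline(
    *,
    tree: Tree | None = None,
    trait_table: TraitTable | None = None,
    alignment: Alignment | None = None,
    environment: pd.DataFrame | None = None,
    fixture_config: FixtureConfig | None = None,
    tree_path=None,
    traits_path=None,
    alignment_path=None,
    env_path=None,
    out_dir=None,
    seed: int = 0,
    permutations: int = 999,
    pgls_mode: str = "fixed-bm",
) -> AnalysisReport:
    """Execute the full comparative analysis and (optionally) write the
    report files.

    Inputs may be in-memory objects, file paths, or -- if neither is
    given -- a synthetic fixture generated from ``fixture_config``.
    Deterministic given inputs and ``seed`` (used for the permutation
    test).
    """
    report = AnalysisReport()
    rng = np.random.default_rng(seed)

    # ---- resolve inputs -------------------------------------------------
    if tree_path is not None:
        tree = parse_newick(Path(tree_path).read_text())
    if traits_path is not None:
        trait_table = traits.read_trait_table(traits_path)
    if alignment_path is not None:
        alignment = read_fasta(alignment_path)
    if env_path is not None:
        environment = traits.read_environment(env_path)
    fixture: Fixture | None = None
    if tree is None and trait_table is None:
        fixture = simulate_fixture(fixture_config or FixtureConfig(seed=seed))
        tree = fixture.tree
        trait_table = fixture.traits
        alignment = fixture.alignment
        environment = fixture.environment
    if tree is None or trait_table is None:
        raise ValueError("a tree and a trait table are required")

    trait_table = traits.complete_cases(trait_table)
    logt = traits.log10_table(trait_table)
    C = tree_vcv(tree)
    missing = set(trait_table.species) - set(C.labels)
    if missing:
        raise ValueError(f"species missing from the tree: {sorted(missing)}")
    C = C.subset(list(trait_table.species))

    report.provenance = {
        "n_species": trait_table.n,
        "seed": seed,
        "permutations": permutations,
        "pgls_mode": pgls_mode,
        "phylo_distance_source": "tn93" if alignment is not None else "patristic",
        "tree_fingerprint": _fingerprint(str(tree.lengths) + str(tree.labels)),
        "traits_fingerprint": _fingerprint(trait_table.data.to_csv()),
        "multiple_testing": "none applied",
        "synthetic": fixture is not None,
    }
    if fixture is not None:
        report.provenance["fixture_config"] = json.loads(fixture.config.to_json())

    # ---- spectrum -------------------------------------------------------
    spec = None
    try:
        spec = spectrum.fit_spectrum(logt)
        groups = spectrum.group_mean_pass(spec.pass_scores, logt)
        report.spectrum = {
            "loadings": spec.loadings,
            "variance_fractions": spec.variance_fractions,
            "axis1_percent": float(spec.variance_fractions[0] * 100.0),
            "axis2_percent": float(spec.variance_fractions[1] * 100.0),
            "pass": spec.pass_scores,
            "cell_stats": groups.cell_stats,
            "cross_habit_pass_distance": groups.cross_habit_distance,
        }
    except Exception as exc:  # stage isolation
        logger.exception("spectrum stage failed")
        report.failures["spectrum"] = str(exc)

    # ---- evolution models ----------------------------------------------
    try:
        sig_rows, evo_rows = [], []
        lambdas, alphas = [], []
        for trait in TRAIT_COLUMNS:
            x = logt.data[trait]
            sig = evomodels.lambda_fit(C, x)
            bm = evomodels.bm_fit(C, x)
            ou = evomodels.ou_fit(C, x)
            lrt = evomodels.bm_vs_ou_lrt(bm, ou)
            sig_rows.append(
                {"trait": trait, "lambda": sig.lambda_hat,
                 "loglik": sig.loglik, "P0": sig.p0, "P1": sig.p1}
            )
            evo_rows.append(
                {"trait": trait, "loglik_BM": bm.loglik, "alpha": ou.alpha,
                 "loglik_OU": ou.loglik, "lrt_p": lrt.p_value}
            )
            lambdas.append(sig.lambda_hat)
            alphas.append(ou.alpha)
        extra = {}
        if spec is not None:
            sig_pass = evomodels.lambda_fit(C, spec.pass_scores)
            extra = {"pass_lambda": sig_pass.lambda_hat,
                     "pass_P0": sig_pass.p0, "pass_P1": sig_pass.p1}
        r_raw, p_raw = evomodels.signal_rate_correlation(lambdas, alphas)
        r_log, p_log = evomodels.signal_rate_correlation(
            lambdas, alphas, log10_alpha=True
        )
        report.evolution = {
            "signal": pd.DataFrame(sig_rows).set_index("trait"),
            "models": pd.DataFrame(evo_rows).set_index("trait"),
            "alpha_lambda_r": r_raw,
            "alpha_lambda_p": p_raw,
            "alpha_lambda_r_log10": r_log,
            "alpha_lambda_p_log10": p_log,
            **extra,
        }
    except Exception as exc:
        logger.exception("evolution stage failed")
        report.failures["evolution"] = str(exc)

    # ---- PGLS -----------------------------------------------------------
    try:
        group_table = pgls.pgls_group_table(trait_table, C, mode=pgls_mode)
        corr = pd.DataFrame(
            np.nan, index=list(TRAIT_COLUMNS), columns=list(TRAIT_COLUMNS)
        )
        n = trait_table.n
        for i, ta in enumerate(TRAIT_COLUMNS):
            for tb in TRAIT_COLUMNS[i + 1:]:
                r = pgls.pgls_correlation(
                    logt.data[ta], logt.data[tb], C, mode=pgls_mode
                )
                corr.loc[tb, ta] = r
        block = {"group_table": group_table, "correlations": corr}
        if spec is not None and environment is not None:
            block["pass_environment"] = pass_environment_fits(
                spec.pass_scores, environment, trait_table, C, mode=pgls_mode
            )
        report.pgls = block
    except Exception as exc:
        logger.exception("pgls stage failed")
        report.failures["pgls"] = str(exc)

    # ---- environment ANOVA ---------------------------------------------
    if environment is not None:
        try:
            rows = []
            for var in ENV_VARIABLES:
                res = anova_by_group(
                    environment[var], environment["elevation"], log10_first=True
                )
                rows.append(
                    {"variable": var, "F": res.F, "p": res.p,
                     "degenerate": res.degenerate}
                )
            report.environment = {
                "anova": pd.DataFrame(rows).set_index("variable")
            }
        except Exception as exc:
            logger.exception("environment stage failed")
            report.failures["environment"] = str(exc)

    # ---- distance regressions -------------------------------------------
    try:
        if spec is None:
            raise RuntimeError("spectrum stage failed; no PASS scores")
        if alignment is not None:
            dm = pairwise_tn93(alignment)
        else:
            dm = patristic_distances(tree)
        # restrict to analysed species
        keep = [dm.labels.index(s) for s in trait_table.species]
        idx = np.array(keep)
        dm = DistanceMatrix(
            labels=tuple(trait_table.species),
            D=dm.D[np.ix_(idx, idx)],
            undefined=None if dm.undefined is None else dm.undefined[np.ix_(idx, idx)],
        )
        results = {}
        for pair_filter in ("all", "intra_elevation_habit_cross"):
            pairs = spectrum.build_pairs(
                trait_table.species,
                pair_filter=pair_filter,
                habit=trait_table.habit(),
                elevation=trait_table.elevation(),
            )
            econ = spectrum.pass_distance(spec.pass_scores, pairs)
            phylo_d = np.array([dm.get(a, b) for a, b in pairs])
            ok = ~np.isnan(phylo_d)
            reg = spectrum.distance_regression(
                econ[ok],
                phylo_d[ok],
                [p for p, o in zip(pairs, ok) if o],
                pair_filter=pair_filter,
                permutations=permutations,
                scores=spec.pass_scores,
                phylo_matrix=dm,
                rng=rng,
            )
            results[pair_filter] = {
                "r": reg.r, "p": reg.p, "slope": reg.slope,
                "intercept": reg.intercept, "n_pairs": reg.n_pairs,
                "permutation_p": reg.permutation_p,
                "n_permutations": reg.n_permutations,
            }
        report.distance = {
            "source": report.provenance["phylo_distance_source"],
            **results,
        }
        report._distance_matrix = dm  # type: ignore[attr-defined]
    except Exception as exc:
        logger.exception("distance stage failed")
        report.failures["distance"] = str(exc)

    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: AnalysisReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if report.spectrum:
        report.spectrum["loadings"].to_csv(out / "spectrum_loadings.tsv", sep="\t")
        pd.Series(
            report.spectrum["variance_fractions"],
            index=[f"PC{k+1}" for k in range(len(report.spectrum["variance_fractions"]))],
            name="variance_fraction",
        ).to_csv(out / "spectrum_variance.tsv", sep="\t")
        report.spectrum["pass"].to_csv(out / "pass_scores.tsv", sep="\t", header=True)
        report.spectrum["cell_stats"].to_csv(
            out / "pass_group_means.tsv", sep="\t", index=False
        )
    if report.evolution:
        report.evolution["signal"].to_csv(out / "signal_lambda.tsv", sep="\t")
        report.evolution["models"].to_csv(out / "evo_models.tsv", sep="\t")
    if report.pgls:
        report.pgls["group_table"].to_csv(out / "pgls_group_table.tsv", sep="\t")
        corr = report.pgls["correlations"]
        starred = corr.copy().astype(object)
        for a in corr.index:
            for b in corr.columns:
                v = corr.loc[a, b]
                if pd.isna(v):
                    starred.loc[a, b] = ""
                else:
                    # two-sided t test of the GLS correlation
                    n = report.provenance["n_species"]
                    t = v * np.sqrt((n - 2) / max(1e-12, 1 - v * v))
                    p = 2 * stats.t.sf(abs(t), n - 2)
                    starred.loc[a, b] = f"{v:.2f}{significance_stars(p)}"
        starred.to_csv(out / "pgls_correlations.tsv", sep="\t")
        if "pass_environment" in report.pgls:
            report.pgls["pass_environment"].to_csv(
                out / "pass_environment.tsv", sep="\t", index=False
            )
    if report.environment:
        report.environment["anova"].to_csv(out / "environment_anova.tsv", sep="\t")
    dm = getattr(report, "_distance_matrix", None)
    if dm is not None:
        write_distance_matrix(dm, out / "phylo_distances.tsv")
    (out / "summary.json").write_text(json.dumps(report.summary(), indent=2))
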