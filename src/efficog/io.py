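"""File formats, run configuration, and the end-to-end pipeline driver.

The pipeline mirrors the study's analysis order: connectome efficiency over
a density sweep, factor analysis of cognitive and attainment scores with
parallel analysis, covariate residualization, the nuisance-variable screen,
the three standardized regressions, the mediation model, and the regional
nodal-efficiency association maps.  Every stage draws its randomness from a
seed spawned deterministically from the top-level seed, so a rerun with the
same configuration is numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .factors import MLFactorAnalysis, residualize, screen_outliers, zscore
from .inference import (
    MediationResult,
    mediation,
    nuisance_regressions,
    regional_association,
    simple_regression_standardized,
)
from .networks import EfficiencyTransformer, WeightedNetwork, default_densities
from .simulate import CohortSpec, SyntheticCohort, sample_cohort

logger = logging.getLogger("efficog")

__all__ = ["RunConfig", "read_matrix_csv", "write_matrix_csv", "write_cohort", "run_pipeline"]


def read_matrix_csv(path: str | Path) -> WeightedNetwork:
    """Read a square labelled CSV as a weighted network.

    The header and the first column must carry identical region labels.
    Asymmetric input is symmetrized by averaging with a logged warning;
    negative entries are rejected.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row labels do not match column headers")
    try:
        w = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric entries") from err
    if np.any(~np.isfinite(w)):
        raise ValueError(f"{path}: non-finite entries")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise ValueError(f"{path}: negative weight at row {df.index[i]}, col {df.columns[j]}")
    if not np.allclose(w, w.T, atol=1e-12):
        logger.warning("%s: asymmetric matrix symmetrized by averaging", path)
        w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(tuple(str(c) for c in df.columns), w)


def write_matrix_csv(net: WeightedNetwork, path: str | Path) -> None:
    pd.DataFrame(net.weights, index=net.labels, columns=net.labels).to_csv(path)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write per-subject connectome CSVs, the cohort table, and the truth JSON."""
    out = Path(out_dir)
    mat_dir = out / "connectomes"
    mat_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sid, net in zip(cohort.subject_ids, cohort.connectomes):
        p = mat_dir / f"{sid}.csv"
        write_matrix_csv(net, p)
        manifest.append((sid, str(p)))
    pd.DataFrame(manifest, columns=["subject", "path"]).to_csv(out / "manifest.csv", index=False)
    pd.concat([cohort.scores, cohort.nuisance], axis=1).to_csv(out / "cohort.csv")
    if cohort.truth is not None:
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in cohort.truth.items()
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of an end-to-end run."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    densities: tuple[float, ...] = tuple(default_densities())
    length_map: str = "inverse"
    n_permutations: int = 10_000
    null_summary: str = "mean"
    n_bootstrap_loadings: int = 0
    n_boot_mediation: int = 5000
    n_boot_regression: int = 500

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        cohort = d.pop("cohort", None)
        if cohort is not None:
            for key in ("cognitive_loadings", "attainment_loadings", "densities"):
                if cohort.get(key) is not None:
                    cohort[key] = tuple(cohort[key])
            d["cohort"] = CohortSpec(**cohort)
        if d.get("densities") is not None:
            d["densities"] = tuple(d["densities"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds, each below 2^31."""
    states = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in states]


def _mediation_to_dict(res: MediationResult) -> dict:
    return {
        "a": res.a,
        "b": res.b,
        "c": res.c,
        "c_prime": res.c_prime,
        "indirect": res.indirect,
        "indirect_ci": list(res.indirect_ci),
        "proportion_mediated": res.proportion_mediated,
        "p_a": res.p_a,
        "p_b": res.p_b,
        "p_c": res.p_c,
        "p_c_prime": res.p_c_prime,
        "partial_mediation": res.partial_mediation,
        "n_boot": res.n_boot,
    }


def run_pipeline(
    config: RunConfig,
    cohort: SyntheticCohort | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full analysis and return the run report as a dict.

    When ``cohort`` is None a synthetic cohort is generated from
    ``config.cohort`` (reseeded from the top-level seed).  With ``out_dir``
    set, every intermediate artifact is written as tidy CSV/JSON.
    """
    t0 = time.perf_counter()
    seeds = _spawn_seeds(config.seed, 5)
    timings: dict[str, float] = {}
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    def _stage(name):
        timings[name] = time.perf_counter()

    try:
        _stage("simulate")
        if cohort is None:
            spec = replace(config.cohort, seed=seeds[0], densities=tuple(config.densities))
            cohort = sample_cohort(spec)
        timings["simulate"] = time.perf_counter() - timings["simulate"]

        _stage("efficiency")
        eff = EfficiencyTransformer(densities=config.densities, length_map=config.length_map)
        eff_table = eff.fit_transform(cohort.connectomes)
        eff_table.index = pd.Index(cohort.subject_ids, name="subject")
        timings["efficiency"] = time.perf_counter() - timings["efficiency"]

        _stage("efa")
        factor_models: dict[str, MLFactorAnalysis] = {}
        fscores: dict[str, np.ndarray] = {}
        outlier_report: dict[str, dict] = {}
        for domain, cols in (
            ("cognitive", cohort.cognitive_columns),
            ("attainment", cohort.attainment_columns),
        ):
            block = cohort.scores[cols]
            z = zscore(block)
            uni, multi = screen_outliers(z)
            outlier_report[domain] = {
                "univariate": int(uni.sum()),
                "multivariate": int(multi.sum()),
            }
            model = MLFactorAnalysis(
                n_factors="parallel",
                n_permutations=config.n_permutations,
                null_summary=config.null_summary,
                n_bootstrap=config.n_bootstrap_loadings,
                random_state=seeds[1],
            ).fit(block)
            factor_models[domain] = model
            raw = model.transform(block)[:, 0]
            fscores[domain] = residualize(
                raw, cohort.nuisance["age"].to_numpy(), cohort.nuisance["sex"].to_numpy()
            )
        timings["efa"] = time.perf_counter() - timings["efa"]

        _stage("inference")
        eg = eff_table["eg_auc"].to_numpy()
        z_eg = (eg - eg.mean()) / eg.std(ddof=1)
        outcomes = pd.DataFrame(
            {
                "cognitive_factor": fscores["cognitive"],
                "attainment_factor": fscores["attainment"],
                "eg_auc": eg,
            },
            index=eff_table.index,
        )
        nuis_cols = ["age", "age_sq", "brain_volume", "sex", "motion"]
        nuisance_tbl = nuisance_regressions(outcomes, cohort.nuisance[nuis_cols])

        regressions = {}
        for name, (xv, yv) in {
            "cognition_on_eg": (z_eg, fscores["cognitive"]),
            "attainment_on_eg": (z_eg, fscores["attainment"]),
            "attainment_on_cognition": (fscores["cognitive"], fscores["attainment"]),
        }.items():
            r = simple_regression_standardized(
                xv, yv, n_boot=config.n_boot_regression, seed=seeds[2]
            )
            regressions[name] = {
                "beta": r.beta,
                "r_squared": r.r_squared,
                "f": r.f_stat,
                "df": list(r.df),
                "p": r.p_value,
            }

        med = mediation(
            z_eg,
            fscores["cognitive"],
            fscores["attainment"],
            n_boot=config.n_boot_mediation,
            seed=seeds[3],
        )

        ej_cols = [c for c in eff_table.columns if c.startswith("ej_auc_")]
        vol_cols = [f"gm_vol_{c.removeprefix('ej_auc_')}" for c in ej_cols]
        regional = {
            domain: regional_association(
                eff_table[ej_cols], fscores[domain], cohort.nuisance[vol_cols]
            )
            for domain in ("cognitive", "attainment")
        }
        timings["inference"] = time.perf_counter() - timings["inference"]
    except Exception as err:
        raise RuntimeError(f"pipeline failed: {err}") from err

    report.update(
        {
            "n_subjects": len(cohort.subject_ids),
            "n_nodes": cohort.connectomes[0].n_nodes,
            "densities": list(map(float, config.densities)),
            "outliers": outlier_report,
            "factors": {
                domain: {
                    "n_factors": m.n_factors_,
                    "loadings": m.loadings_[:, 0].tolist(),
                    "uniquenesses": m.uniquenesses_.tolist(),
                    "var_explained": m.var_explained_,
                    "rmsr": m.rmsr_,
                    "rmsea": m.rmsea_,
                    "tli": m.tli_,
                }
                for domain, m in factor_models.items()
            },
            "regressions": regressions,
            "mediation": _mediation_to_dict(med),
            "eg_auc_mean": float(eg.mean()),
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
            "runtime_s": round(time.perf_counter() - t0, 4),
        }
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())
        eff_table.to_csv(out / "efficiency_auc.csv")
        outcomes.to_csv(out / "factor_scores.csv")
        nuisance_tbl.to_csv(out / "nuisance_regressions.csv", index=False)
        for domain, tbl in regional.items():
            tbl.to_csv(out / f"regional_association_{domain}.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "report.txt").write_text(_format_report(report))
    report["_tables"] = {
        "nuisance": nuisance_tbl,
        "regional": regional,
        "efficiency": eff_table,
        "outcomes": outcomes,
    }
    return report


def _format_report(report: dict) -> str:
    """Human-readable run summary."""
    lines = [
        f"efficog v{report['version']}  (config {report['config_hash']}, seed {report['seed']})",
        f"subjects: {report['n_subjects']}  nodes: {report['n_nodes']}",
        "",
    ]
    for domain, f in report["factors"].items():
        lines.append(
            f"{domain} factor: k={f['n_factors']}  var explained={f['var_explained']:.2f}  "
            f"RMSR={f['rmsr']:.3f}  RMSEA={f['rmsea']:.3f}  TLI={f['tli']:.3f}"
        )
    lines.append("")
    for name, r in report["regressions"].items():
        lines.append(
            f"{name}: beta={r['beta']:.3f}  R2={r['r_squared']:.3f}  "
            f"F({r['df'][0]},{r['df'][1]})={r['f']:.2f}  p={r['p']:.2g}"
        )
    m = report["mediation"]
    lines += [
        "",
        (
            f"mediation: a={m['a']:.3f} b={m['b']:.3f} c={m['c']:.3f} "
            f"c'={m['c_prime']:.3f} indirect={m['indirect']:.3f} "
            f"CI[{m['indirect_ci'][0]:.3f}, {m['indirect_ci'][1]:.3f}] "
            f"{'partial mediation' if m['partial_mediation'] else ''}"
        ),
        f"runtime: {report['runtime_s']} s",
    ]
    return "\n".join(lines) + "\n"
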