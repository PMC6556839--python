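"""Synthetic cohorts with the causal structure the analysis assumes.

No imaging data are simulated.  Each subject gets an FA-weighted connectome
derived from a shared template by a subject-level "white-matter integrity"
latent s_i: edge weights are the template weights times a logistic squash of
gamma * s_i plus edge noise, which keeps weights FA-like in (0, 1) and makes
global efficiency increase smoothly in s_i.  Cognitive and attainment scores
then follow a single-factor measurement model over latents linked by the
mediation chain

    z(E_G AUC)  --a-->  g  --b-->  attainment,   plus a direct path c'.

All paths are standardized; latent variances are 1, so the spec'd paths are
directly the betas the analysis should recover.  A ``truth`` record carries
the generating latents for recovery tests only — analysis stages never read
it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .networks import WeightedNetwork, default_densities, efficiency_profile

__all__ = ["CohortSpec", "SyntheticCohort", "make_template_network", "sample_cohort"]

# CALM-like defaults: loadings from the one-factor solutions of the clinical
# sample; mediation paths chosen so the implied total effect of efficiency on
# attainment (c' + a*b ~= 0.29) matches the standardized betas the analysis
# model targets.
DEFAULT_COGNITIVE_LOADINGS = (0.75, 0.62, 0.66, 0.82, 0.59)
DEFAULT_ATTAINMENT_LOADINGS = (0.93, 0.91, 0.74)


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for a synthetic cohort.

    ``integrity_effect`` (gamma) scales how strongly the subject latent
    perturbs connectome weights; its default is arbitrary in magnitude (the
    study measured real brains and reports no such variance component) and
    is documented as such.
    """

    n_subjects: int = 139
    n_nodes: int = 85
    template_density: float = 0.7
    integrity_effect: float = 1.0
    path_a: float = 0.34
    path_b: float = 0.55
    path_cprime: float = 0.10
    cognitive_loadings: tuple[float, ...] = DEFAULT_COGNITIVE_LOADINGS
    attainment_loadings: tuple[float, ...] = DEFAULT_ATTAINMENT_LOADINGS
    noise_sd: float = 1.0
    age_coupling: float = 0.0
    densities: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if not 0 < self.template_density <= 1:
            raise ValueError("template_density must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for lam in (*self.cognitive_loadings, *self.attainment_loadings):
            if not 0 < lam < 1:
                raise ValueError(f"loadings must lie in (0, 1), got {lam}")
        if self.path_a**2 + self.age_coupling**2 > 1:
            raise ValueError("path_a^2 + age_coupling^2 must not exceed 1")
        implied = (
            self.path_b**2
            + self.path_cprime**2
            + 2 * self.path_a * self.path_b * self.path_cprime
        )
        if implied > 1:
            raise ValueError(
                f"implied attainment variance {implied:.3f} exceeds 1; shrink the paths"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        for key in ("cognitive_loadings", "attainment_loadings", "densities"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    subject_ids: list[str]
    connectomes: list[WeightedNetwork]
    scores: pd.DataFrame  # cognitive cog_* and attainment edu_* columns
    nuisance: pd.DataFrame  # age, age_sq, sex, motion, brain_volume, gm_vol_*
    truth: dict | None = field(default=None, repr=False)

    def drop_truth(self) -> "SyntheticCohort":
        """Copy with the truth channel removed; analysis must not change."""
        return SyntheticCohort(
            self.spec, self.subject_ids, self.connectomes, self.scores, self.nuisance, None
        )

    @property
    def cognitive_columns(self) -> list[str]:
        return [c for c in self.scores.columns if c.startswith("cog_")]

    @property
    def attainment_columns(self) -> list[str]:
        return [c for c in self.scores.columns if c.startswith("edu_")]


def make_template_network(
    n_nodes: int, template_density: float, seed: int | np.random.Generator = 0
) -> WeightedNetwork:
    """Random geometric template connectome.

    Nodes get random 3-d coordinates; edges are drawn with probability
    decreasing in Euclidean distance (short-range connections dominate, as
    in real white matter), the strongest-probability draws are kept until
    the target edge count is met, and any edges of the spatial minimum
    spanning tree missing afterwards are added so the template is connected.
    Weights are beta-distributed in (0.2, 0.7) to mimic tract-average FA.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if not 0 < template_density <= 1:
        raise ValueError("template_density must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    coords = rng.uniform(0, 1, size=(n_nodes, 3))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu, ju = np.triu_indices(n_nodes, k=1)
    n_possible = iu.size
    k = int(np.floor(template_density * n_possible + 0.5))

    # Gumbel-trick sampling without replacement, proportional to exp(-d/0.3)
    logits = -dist[iu, ju] / 0.3
    keys = logits + rng.gumbel(size=n_possible)
    chosen = np.argsort(keys)[::-1][:k]
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    adj[iu[chosen], ju[chosen]] = True

    mst = minimum_spanning_tree(dist).toarray() > 0
    adj |= mst | mst.T
    adj |= adj.T

    weights = np.zeros((n_nodes, n_nodes))
    vals = 0.2 + 0.5 * rng.beta(4, 4, size=n_possible)
    sel = adj[iu, ju]
    weights[iu[sel], ju[sel]] = vals[sel]
    weights = weights + weights.T

    n_comp, _ = connected_components(weights > 0, directed=False)
    assert n_comp == 1, "MST repair must leave the template connected"
    return WeightedNetwork.from_array(weights)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def sample_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort under ``spec``; bit-identical per seed."""
    rng = np.random.default_rng(spec.seed)
    n, p_nodes = spec.n_subjects, spec.n_nodes
    template = make_template_network(p_nodes, spec.template_density, rng)
    densities = (
        default_densities() if spec.densities is None else np.asarray(spec.densities, float)
    )

    s = rng.standard_normal(n)
    iu, ju = np.triu_indices(p_nodes, k=1)
    tpl_edges = template.weights[iu, ju]
    connectomes: list[WeightedNetwork] = []
    eg_auc = np.empty(n)
    for i in range(n):
        eps = rng.normal(0.0, spec.noise_sd, size=iu.size)
        scale = _logistic(spec.integrity_effect * s[i] + eps)
        edge_w = np.clip(tpl_edges * scale, 0.0, 1.0)
        w = np.zeros((p_nodes, p_nodes))
        w[iu, ju] = edge_w
        w = w + w.T
        net = WeightedNetwork(template.labels, w)
        connectomes.append(net)
        eg_auc[i] = efficiency_profile(net, densities).auc_global

    z_eg = (eg_auc - eg_auc.mean()) / eg_auc.std(ddof=1)

    age = rng.uniform(7.0, 12.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    motion = rng.lognormal(mean=-1.0, sigma=0.5, size=n)  # mm, median ~0.37
    brain_vol = rng.normal(1.2e6, 1.0e5, size=n)  # mm^3
    gm_vol = np.abs(rng.normal(5000.0, 1000.0, size=(n, p_nodes)))  # mm^3 per region

    a, b, cp = spec.path_a, spec.path_b, spec.path_cprime
    z_age = (age - age.mean()) / age.std(ddof=1)
    g_resid_sd = np.sqrt(1.0 - a**2 - spec.age_coupling**2)
    g = a * z_eg + spec.age_coupling * z_age + g_resid_sd * rng.standard_normal(n)
    y_resid_sd = np.sqrt(1.0 - (b**2 + cp**2 + 2 * a * b * cp))
    y = b * g + cp * z_eg + y_resid_sd * rng.standard_normal(n)

    def observe(latent: np.ndarray, loadings: Sequence[float], prefix: str) -> pd.DataFrame:
        cols = {}
        for j, lam in enumerate(loadings):
            noise = rng.standard_normal(n)
            cols[f"{prefix}_{j + 1:02d}"] = lam * latent + np.sqrt(1 - lam**2) * noise
        return pd.DataFrame(cols)

    subject_ids = [f"sub_{i + 1:04d}" for i in range(n)]
    scores = pd.concat(
        [
            observe(g, spec.cognitive_loadings, "cog"),
            observe(y, spec.attainment_loadings, "edu"),
        ],
        axis=1,
    )
    scores.index = pd.Index(subject_ids, name="subject")
    nuisance = pd.DataFrame(
        {
            "age": age,
            "age_sq": age**2,
            "sex": sex,
            "motion": motion,
            "brain_volume": brain_vol,
        },
        index=scores.index,
    )
    for j, lab in enumerate(template.labels):
        nuisance[f"gm_vol_{lab}"] = gm_vol[:, j]

    truth = {
        "s": s,
        "g": g,
        "attainment": y,
        "eg_auc": eg_auc,
        "z_eg_auc": z_eg,
        "spec": asdict(spec),
    }
    return SyntheticCohort(spec, subject_ids, connectomes, scores, nuisance, truth)
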