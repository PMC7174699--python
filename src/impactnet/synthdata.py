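"""Seeded synthetic parcellations, connectome cohorts, and impact datasets.

The real inputs to this analysis — professional-football impact
reconstructions run through a finite-element head model, and diffusion
imaging connectomes for 30 healthy adults — are not public.  This module
generates datasets with the statistical structure the analysis assumes, at
the study's native scale (a 129-region parcellation, 30 subjects, 53
impacts of which 20 were concussive), together with a ground-truth record
so that recovery of the planted structure can be tested.

The generative model, briefly:

* **Atlas** — ``n`` regions split into cortical and subcortical tissue over
  two hemispheres.  Network hubs are planted among subcortical regions and
  high-strain regions among cortical ones, disjoint by default, mirroring
  the empirical pattern that deformation concentrates in lateral cortex
  while communication bottlenecks sit in subcortex.

* **Connectome** — modular random graph with log-normal edge weights
  emulating volume-normalized streamline counts.  Intra-module edges are
  ``intra_module_bias`` times more likely than inter-module ones.  Planted
  hubs attach with ``hub_weight_boost``-fold probability *and* carry
  ``hub_weight_boost``-fold edge weights, which gives them both high degree
  and high strength — the two properties that make single-node deletion
  costly for global efficiency.  Graphs are rejection-sampled until
  connected.

* **Cohort** — one shared base connectome perturbed per subject by
  mean-one log-normal edge noise, so between-subject edge variability
  grows monotonically with ``between_subject_noise``.

* **Impacts** — a single latent per-case severity drives all four peak
  kinematics and the strain field, each with independent multiplicative
  log-normal noise.  Concussive cases have their severity multiplied by
  ``concussion_strain_shift``, making both kinematics and strains
  stochastically larger.  Per region, 200 element strains are drawn from a
  gamma distribution scaled by the region's base profile (elevated in the
  planted high-strain regions) and the case severity; rMPS is the
  region-wise 95th percentile and MPS95 the 95th percentile of the pooled
  element sample.  The channel noise is derived in closed form from
  ``kinematic_strain_coupling`` so that the sample correlation between
  MPS95 and peak angular acceleration lands near the requested value.

All generators are deterministic: identical arguments and seed give
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .netcore import Connectome
from .strain import CONCUSSION, NO_CONCUSSION, ImpactCase, percentile95

HEMISPHERES = ("L", "R", "midline")
TISSUE_CLASSES = ("cortical", "subcortical")
PLANTED_ROLES = ("hub", "lateral_high_strain", "neither", "both")

_CORTICAL_NAMES = (
    "precentral", "postcentral", "superior temporal", "supramarginal",
    "insula", "pars opercularis", "posterior cingulate", "pericalcarine",
    "superior frontal", "lateral occipital", "precuneus", "fusiform",
)
_SUBCORTICAL_NAMES = (
    "caudate", "putamen", "thalamus", "hippocampus", "pallidum",
    "amygdala", "accumbens",
)

#: latent log-severity spread shared by all generated impact datasets
SEVERITY_LOG_SD = 0.35
#: element strains per region per case (emulates an FE mesh sample)
N_ELEMENTS = 200
#: gamma shape of the within-region element-strain distribution
ELEMENT_GAMMA_SHAPE = 6.0
#: log-sd of the static between-region strain profile
PROFILE_LOG_SD = 0.15
#: multiplicative elevation of the planted high-strain regions
STRAIN_REGION_BOOST = 2.0
#: typical whole-brain strain scale (dimensionless strain)
BASE_STRAIN = 0.15
#: channel scales for (lin vel m/s, ang vel rad/s, lin acc g, ang acc rad/s^2)
KINEMATIC_SCALES = (8.0, 40.0, 80.0, 5000.0)


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a constraint."""


class ParameterError(ValueError):
    """Raised for invalid generator arguments; names the offending one."""


@dataclass(frozen=True)
class ParcellationAtlas:
    """Synthetic region table standing in for a 129-region brain atlas."""

    region_ids: tuple[int, ...]
    region_names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    tissue_classes: tuple[str, ...]
    planted_roles: tuple[str, ...]

    def __post_init__(self):
        n = len(self.region_ids)
        if self.region_ids != tuple(range(n)):
            raise ParameterError("region_ids must be contiguous from 0")
        for name, values, allowed in (
            ("hemispheres", self.hemispheres, HEMISPHERES),
            ("tissue_classes", self.tissue_classes, TISSUE_CLASSES),
            ("planted_roles", self.planted_roles, PLANTED_ROLES),
        ):
            if len(values) != n:
                raise ParameterError(f"{name} must have one entry per region")
            bad = set(values) - set(allowed)
            if bad:
                raise ParameterError(f"{name} contains invalid labels {bad}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def hub_ids(self) -> tuple[int, ...]:
        return tuple(
            r for r, role in zip(self.region_ids, self.planted_roles)
            if role in ("hub", "both")
        )

    @property
    def high_strain_ids(self) -> tuple[int, ...]:
        return tuple(
            r for r, role in zip(self.region_ids, self.planted_roles)
            if role in ("lateral_high_strain", "both")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "name": self.region_names,
                "hemisphere": self.hemispheres,
                "tissue_class": self.tissue_classes,
                "planted_role": self.planted_roles,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ParcellationAtlas":
        return cls(
            tuple(int(r) for r in frame["region_id"]),
            tuple(str(v) for v in frame["name"]),
            tuple(str(v) for v in frame["hemisphere"]),
            tuple(str(v) for v in frame["tissue_class"]),
            tuple(str(v) for v in frame["planted_role"]),
        )


@dataclass(frozen=True)
class GroundTruth:
    """What was planted in a generated dataset, for recovery tests."""

    hub_ids: tuple[int, ...]
    high_strain_ids: tuple[int, ...]
    concussion_strain_shift: float
    kinematic_strain_coupling: float
    seed: int

    def __post_init__(self):
        if self.concussion_strain_shift <= 0:
            raise ParameterError("concussion_strain_shift must be positive")
        if not 0 < self.kinematic_strain_coupling <= 1:
            raise ParameterError("kinematic_strain_coupling must be in (0, 1]")
        object.__setattr__(self, "hub_ids", tuple(int(r) for r in self.hub_ids))
        object.__setattr__(
            self, "high_strain_ids", tuple(int(r) for r in self.high_strain_ids)
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["hub_ids"]), tuple(d["high_strain_ids"]),
            d["concussion_strain_shift"], d["kinematic_strain_coupling"], d["seed"],
        )


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def gen_atlas(
    n_regions: int, n_hubs: int, n_strain_regions: int, seed: int,
    allow_overlap: bool = False,
) -> ParcellationAtlas:
    """Generate a parcellation with planted hub and high-strain regions.

    Hubs are drawn from subcortical regions and high-strain regions from
    cortical ones; the two sets are disjoint unless ``allow_overlap``.
    """
    if n_regions < 1:
        raise ParameterError(f"n_regions must be positive, got {n_regions}")
    if n_hubs < 1:
        raise ParameterError(f"n_hubs must be positive, got {n_hubs}")
    if n_strain_regions < 1:
        raise ParameterError(
            f"n_strain_regions must be positive, got {n_strain_regions}"
        )
    if n_hubs + n_strain_regions > n_regions:
        raise ParameterError(
            f"n_hubs + n_strain_regions = {n_hubs + n_strain_regions} "
            f"exceeds n_regions = {n_regions}"
        )
    rng = _rng(seed, 0)
    # roughly a quarter subcortical, as in real hierarchical atlases, but
    # always enough subcortex to host the hubs (and cortex for the strain set)
    n_sub = min(max(n_regions // 4, n_hubs), n_regions - n_strain_regions)
    tissue = np.array(["cortical"] * n_regions, dtype=object)
    sub_idx = rng.choice(n_regions, size=n_sub, replace=False)
    tissue[sub_idx] = "subcortical"
    cort_idx = np.flatnonzero(tissue == "cortical")

    hubs = set(rng.choice(sub_idx, size=n_hubs, replace=False).tolist())
    if allow_overlap:
        strain_pool = cort_idx
    else:
        strain_pool = np.array([i for i in cort_idx if i not in hubs])
    strain = set(rng.choice(strain_pool, size=n_strain_regions, replace=False).tolist())

    roles, names, hemis = [], [], []
    counters: dict[str, int] = {}
    for i in range(n_regions):
        in_hub, in_strain = i in hubs, i in strain
        roles.append(
            "both" if in_hub and in_strain
            else "hub" if in_hub
            else "lateral_high_strain" if in_strain
            else "neither"
        )
        hemi = "L" if i % 2 == 0 else "R"
        pool = _SUBCORTICAL_NAMES if tissue[i] == "subcortical" else _CORTICAL_NAMES
        base = pool[int(rng.integers(len(pool)))]
        key = f"{hemi}:{base}"
        counters[key] = counters.get(key, 0) + 1
        names.append(f"{hemi}H {base} {counters[key]}")
        hemis.append(hemi)
    return ParcellationAtlas(
        tuple(range(n_regions)), tuple(names), tuple(hemis),
        tuple(str(t) for t in tissue), tuple(roles),
    )


def _module_assignment(n: int, n_modules: int) -> np.ndarray:
    return np.arange(n) % n_modules


def gen_connectome(
    atlas: ParcellationAtlas,
    density: float = 0.15,
    hub_weight_boost: float = 3.0,
    intra_module_bias: float = 2.0,
    seed: int = 0,
    n_modules: int = 4,
    max_attempts: int = 50,
) -> Connectome:
    """Generate a weighted, connected, modular synthetic connectome.

    ``density`` is the expected edge density for non-hub pairs;
    ``hub_weight_boost`` multiplies both the attachment probability and the
    edge weight of planted hubs; ``intra_module_bias`` favors within-module
    edges.  Rejection-samples until the graph is connected.
    """
    if not 0 < density <= 1:
        raise ParameterError(f"density must be in (0, 1], got {density}")
    if hub_weight_boost < 1:
        raise ParameterError(f"hub_weight_boost must be >= 1, got {hub_weight_boost}")
    if intra_module_bias < 1:
        raise ParameterError(f"intra_module_bias must be >= 1, got {intra_module_bias}")
    n = atlas.n_regions
    modules = _module_assignment(n, n_modules)
    hubs = np.zeros(n, dtype=bool)
    hubs[list(atlas.hub_ids)] = True

    same = modules[:, None] == modules[None, :]
    f_intra = same[np.triu_indices(n, 1)].mean() if n > 1 else 0.0
    # choose the inter-module probability so overall (non-hub) density is met
    p_inter = density / ((1 - f_intra) + intra_module_bias * f_intra)
    prob = np.where(same, min(1.0, intra_module_bias * p_inter), p_inter)
    hub_pair = hubs[:, None] | hubs[None, :]
    prob = np.where(hub_pair, np.minimum(1.0, prob * hub_weight_boost), prob)

    for attempt in range(max_attempts):
        rng = _rng(seed, 1, attempt)
        upper = np.triu(rng.random((n, n)) < prob, k=1)
        w = np.zeros((n, n))
        weights = np.exp(rng.normal(0.0, 0.5, size=int(upper.sum())))
        w[upper] = weights
        w[upper & hub_pair] *= hub_weight_boost
        w = w + w.T
        if n == 1:
            return Connectome(w, atlas.region_ids, f"synthetic-{seed}")
        n_comp, _ = connected_components(w > 0, directed=False)
        if n_comp == 1:
            return Connectome(w, atlas.region_ids, f"synthetic-{seed}")
    raise GenerationError(
        f"no connected graph after {max_attempts} attempts "
        f"(density={density}, n={n}); raise density or max_attempts"
    )


def gen_cohort(
    atlas: ParcellationAtlas,
    n_subjects: int,
    between_subject_noise: float = 0.3,
    seed: int = 0,
    **connectome_kwargs,
) -> list[Connectome]:
    """A cohort of subject connectomes sharing one atlas and hub plan.

    A base connectome (identical to ``gen_connectome`` at the same seed and
    keyword arguments) is perturbed per subject with mean-one multiplicative
    log-normal edge noise of log-sd ``between_subject_noise``; zero noise
    yields identical subjects.
    """
    if n_subjects < 1:
        raise ParameterError(f"n_subjects must be >= 1, got {n_subjects}")
    if between_subject_noise < 0:
        raise ParameterError(
            f"between_subject_noise must be >= 0, got {between_subject_noise}"
        )
    base = gen_connectome(atlas, seed=seed, **connectome_kwargs)
    sigma = between_subject_noise
    subjects = []
    n = base.n
    iu = np.triu_indices(n, 1)
    for s in range(n_subjects):
        rng = _rng(seed, 2, s)
        factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=iu[0].size))
        w = np.array(base.weights)
        upper = np.zeros((n, n))
        upper[iu] = w[iu] * factors
        w = upper + upper.T
        subjects.append(Connectome(w, base.region_ids, base.atlas_ref))
    return subjects


def make_ground_truth(
    atlas: ParcellationAtlas,
    concussion_strain_shift: float = 1.5,
    kinematic_strain_coupling: float = 0.83,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth with the planted sets of ``atlas`` and default effects.

    The default coupling of 0.83 between whole-brain strain and peak
    angular acceleration, and a 1.5-fold concussive severity elevation,
    give impact datasets whose kinematics separate outcomes about as
    cleanly as real reconstructed football impacts do.
    """
    return GroundTruth(
        atlas.hub_ids, atlas.high_strain_ids,
        concussion_strain_shift, kinematic_strain_coupling, int(seed),
    )


def gen_impacts(
    atlas: ParcellationAtlas,
    n_cases: int,
    n_concussive: int,
    truth: GroundTruth | None = None,
    seed: int = 0,
    n_elements: int = N_ELEMENTS,
) -> list[ImpactCase]:
    """Generate impact cases with kinematics, rMPS vectors and MPS95.

    Concussive cases are stochastically more severe by the factor
    ``truth.concussion_strain_shift`` applied to the latent severity; at
    shift = 1 outcome labels are independent of every observable (an exact
    null).  See the module docstring for the generative model.
    """
    if n_cases < 1:
        raise ParameterError(f"n_cases must be positive, got {n_cases}")
    if n_concussive > n_cases:
        raise ParameterError(
            f"n_concussive = {n_concussive} exceeds n_cases = {n_cases}"
        )
    if n_concussive < 0:
        raise ParameterError(f"n_concussive must be >= 0, got {n_concussive}")
    if truth is None:
        truth = make_ground_truth(atlas, seed=seed)
    rng = _rng(seed, 3)
    n = atlas.n_regions

    # static between-region strain profile, elevated in the planted regions
    profile = BASE_STRAIN * np.exp(rng.normal(0.0, PROFILE_LOG_SD, size=n))
    planted = np.zeros(n, dtype=bool)
    planted[list(truth.high_strain_ids)] = True
    profile[planted] *= STRAIN_REGION_BOOST

    outcomes = np.array([1] * n_concussive + [0] * (n_cases - n_concussive))
    outcomes = rng.permutation(outcomes)
    delta = np.log(truth.concussion_strain_shift)
    frac = n_concussive / n_cases
    # Channel noise chosen so the *raw-scale* Pearson correlation between
    # MPS95 and peak angular acceleration lands near the requested coupling.
    # Both observables are exp(latent + noise); for jointly log-normal pairs
    # with common latent variance v and per-channel noise s2 - v, the raw
    # correlation is (e^v - 1)/(e^s2 - 1), which we invert for s2.  The
    # concussive/non-concussive mixture contributes f(1-f) delta^2 to v.
    latent_var = SEVERITY_LOG_SD**2 + frac * (1 - frac) * delta**2
    rho = truth.kinematic_strain_coupling
    total_var = float(np.log1p(np.expm1(latent_var) / rho))
    sigma_n = float(np.sqrt(max(total_var - latent_var, 0.0)))

    log_sev = delta * outcomes + rng.normal(0.0, SEVERITY_LOG_SD, size=n_cases)
    kin = np.empty((n_cases, 4))
    for j, scale in enumerate(KINEMATIC_SCALES):
        kin[:, j] = scale * np.exp(log_sev + rng.normal(0.0, sigma_n, size=n_cases))
    strain_mult = np.exp(log_sev + rng.normal(0.0, sigma_n, size=n_cases))

    cases = []
    for i in range(n_cases):
        means = profile * strain_mult[i]
        elements = rng.gamma(
            ELEMENT_GAMMA_SHAPE,
            means[:, None] / ELEMENT_GAMMA_SHAPE,
            size=(n, n_elements),
        )
        rmps = np.percentile(elements, 95, axis=1)
        mps95 = percentile95(elements.ravel())
        cases.append(
            ImpactCase(
                case_id=f"case_{i:03d}",
                outcome=CONCUSSION if outcomes[i] else NO_CONCUSSION,
                peak_lin_vel=float(kin[i, 0]),
                peak_ang_vel=float(kin[i, 1]),
                peak_lin_acc=float(kin[i, 2]),
                peak_ang_acc=float(kin[i, 3]),
                rmps=rmps,
                mps95=mps95,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# dataset IO

def write_connectome(conn: Connectome, path: str | Path) -> None:
    frame = pd.DataFrame(conn.weights, index=conn.region_ids, columns=conn.region_ids)
    frame.to_csv(path, sep="\t", index_label="region_id", float_format="%.10g")


def read_connectome(path: str | Path, atlas_ref: str = "") -> Connectome:
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    ids = tuple(int(c) for c in frame.columns)
    return Connectome(frame.to_numpy(dtype=float), ids, atlas_ref)


def write_dataset(
    out_dir: str | Path,
    atlas: ParcellationAtlas,
    truth: GroundTruth,
    cohort: Sequence[Connectome],
    impacts: Sequence[ImpactCase],
) -> Path:
    """Write a complete synthetic dataset as plain-text files."""
    from .strain import impacts_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas.to_frame().to_csv(out / "atlas.tsv", sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")
    conn_dir = out / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    for i, conn in enumerate(cohort):
        write_connectome(conn, conn_dir / f"subject_{i:02d}.tsv")
    impacts_to_frame(impacts).to_csv(
        out / "impacts.tsv", sep="\t", index=False, float_format="%.10g"
    )
    return out
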