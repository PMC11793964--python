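"""Synthetic landmark datasets with a lineage x period design.

Generates bilaterally symmetric template configurations and specimens with
lineage mean offsets, a period shift, a convergence factor shrinking the
lineage offsets in the modern period, isotropic landmark noise, and a size
structure — then hides it all behind random similarity transforms, so the
whole analysis chain (symmetric GPA -> PCA -> permutation ANOVA -> MCI)
can be exercised and calibrated without any real data.

Effect directions are constructed inside the symmetric shape subspace and
orthogonal to the similarity-transform tangent directions of the template,
so nominal effect sizes survive superimposition approximately unchanged
(an approximation, good in the small-noise regime; ``expected_mci`` is the
matching analytic oracle and is itself validated against brute-force
simulation in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.stats import special_ortho_group

from .landmark_io import LandmarkConfiguration, LandmarkDataset, SymmetryMap
from .superimposition import centroid_size, reflect_relabel

CELLS = (
    ("DE", "historic"),
    ("DE", "modern"),
    ("DL", "historic"),
    ("DL", "modern"),
    ("wild", "historic"),
    ("wild", "modern"),
)

#: Cell sizes of the motivating study design (DE 28/20, DL 23/16, wild 33/15).
DEFAULT_N_PER_CELL = (28, 20, 23, 16, 33, 15)


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters for :func:`simulate_dataset`."""

    k_pairs: int = 6
    k_midline: int = 4
    n_per_cell: tuple[int, ...] = DEFAULT_N_PER_CELL
    lineage_offset: float = 0.08  # d, template length units
    period_shift: float = 0.02  # tau
    convergence: float = 0.0  # c in [-1, 1]; >0 convergence, <0 divergence
    wild_offset: float = 0.3
    noise_sd: float = 0.02  # sigma, per coordinate
    size_mean: tuple[float, ...] = (250.0, 250.0, 250.0, 250.0, 180.0, 180.0)
    size_cv: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.k_pairs + self.k_midline < 4:
            raise ValueError("need k = 2*k_pairs + k_midline >= 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.n_per_cell) != 6 or any(n < 2 for n in self.n_per_cell):
            raise ValueError("n_per_cell must give 6 cell sizes, each >= 2")
        if not -1.0 <= self.convergence <= 1.0:
            raise ValueError("convergence must lie in [-1, 1]")
        if len(self.size_mean) != 6 or any(m <= 0 for m in self.size_mean):
            raise ValueError("size_mean must give 6 positive cell means")

    @property
    def k(self) -> int:
        return 2 * self.k_pairs + self.k_midline


class ExpectedMci(NamedTuple):
    value: float
    in_regime: bool


def make_template(
    k_pairs: int, k_midline: int, seed: int | None = None
) -> tuple[LandmarkConfiguration, SymmetryMap]:
    """Random bilaterally symmetric template mirrored across the x=0 plane."""
    rng = np.random.default_rng(seed)
    right = np.column_stack(
        [
            rng.uniform(0.2, 1.0, k_pairs),
            rng.uniform(-1.0, 1.0, (k_pairs, 2)),
        ]
    )
    left = right * np.array([-1.0, 1.0, 1.0])
    mid = np.column_stack(
        [np.zeros(k_midline), rng.uniform(-1.0, 1.0, (k_midline, 2))]
    )
    coords = np.concatenate([left, right, mid])
    names = (
        [f"L{i + 1}" for i in range(k_pairs)]
        + [f"R{i + 1}" for i in range(k_pairs)]
        + [f"M{i + 1}" for i in range(k_midline)]
    )
    symmetry = SymmetryMap(
        pairs=tuple((i, k_pairs + i) for i in range(k_pairs)),
        midline=tuple(range(2 * k_pairs, 2 * k_pairs + k_midline)),
        reflection_plane="x",
    )
    config = LandmarkConfiguration("template", coords, tuple(names))
    return config, symmetry


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3k, 7) of the similarity-transform tangent
    directions (3 translations, 1 scaling, 3 infinitesimal rotations) at a
    centred template."""
    k = template.shape[0]
    centred = template - template.mean(axis=0)
    cols = []
    for d in range(3):
        t = np.zeros((k, 3))
        t[:, d] = 1.0
        cols.append(t.ravel())
    cols.append(centred.ravel())
    generators = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
    ]
    cols += [(centred @ g.T).ravel() for g in generators]
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def _effect_directions(
    template: np.ndarray, symmetry: SymmetryMap, rng: np.random.Generator, count: int
) -> list[np.ndarray]:
    """Mutually orthonormal unit directions in flattened shape space that
    are symmetric under reflect-relabel and orthogonal to similarity
    transforms of the template."""
    k = template.shape[0]
    basis = _similarity_basis(template)
    taken = [basis[:, j] for j in range(basis.shape[1])]
    out: list[np.ndarray] = []
    while len(out) < count:
        v = rng.standard_normal((k, 3))
        v = 0.5 * (v + reflect_relabel(v, symmetry))
        v = v.ravel()
        for w in taken + out:
            v -= (v @ w) * w
        norm = np.linalg.norm(v)
        if norm < 1e-8:  # pragma: no cover - essentially impossible
            continue
        out.append(v / norm)
    return out


def _cell_means(params: SimulationParams, template_flat: np.ndarray, u, v, w) -> dict:
    d, tau, c = params.lineage_offset, params.period_shift, params.convergence
    sign = {"DE": 1.0, "DL": -1.0, "wild": 0.0}
    means = {}
    for lin, per in CELLS:
        modern = per == "modern"
        mean = template_flat + sign[lin] * d * (1 - c * modern) * u
        if lin == "wild":
            mean = mean + params.wild_offset * w
        if modern:
            mean = mean + tau * v
        means[(lin, per)] = mean
    return means


def simulate_dataset(
    params: SimulationParams,
) -> tuple[LandmarkDataset, dict]:
    """Generate a dataset plus a truth record of all generating structure."""
    rng = np.random.default_rng(params.seed)
    template, symmetry = make_template(
        params.k_pairs, params.k_midline, seed=int(rng.integers(2**31))
    )
    template_flat = (template.coords - template.coords.mean(axis=0)).ravel()
    u, v, w = _effect_directions(template.coords, symmetry, rng, 3)
    means = _cell_means(params, template_flat, u, v, w)

    k = params.k
    all_coords, ids, lineage, period = [], [], [], []
    for cell_idx, (lin, per) in enumerate(CELLS):
        n = params.n_per_cell[cell_idx]
        shapes = means[(lin, per)] + rng.normal(0.0, params.noise_sd, (n, 3 * k))
        shapes = shapes.reshape(n, k, 3)
        rots = special_ortho_group.rvs(3, size=n, random_state=rng)
        if n == 1:  # scipy squeezes size-1 draws
            rots = rots[None]
        shapes = np.einsum("nkd,nde->nke", shapes, rots)
        cs = centroid_size(shapes)
        sigma_ln = np.sqrt(np.log1p(params.size_cv**2))
        mu_ln = np.log(params.size_mean[cell_idx]) - 0.5 * sigma_ln**2
        target = rng.lognormal(mu_ln, sigma_ln, n)
        shapes *= (target / cs)[:, None, None]
        shapes += rng.uniform(-1.0, 1.0, (n, 1, 3)) * params.size_mean[cell_idx]
        all_coords.append(shapes)
        ids += [f"{lin}-{per}-{i + 1:03d}" for i in range(n)]
        lineage += [lin] * n
        period += [per] * n

    dataset = LandmarkDataset(
        coords=np.concatenate(all_coords),
        specimen_ids=tuple(ids),
        landmark_names=template.landmark_names,
        lineage=np.array(lineage, dtype=object),
        period=np.array(period, dtype=object),
        symmetry=symmetry,
    )
    truth = {
        "params": params,
        "template": template,
        "symmetry": symmetry,
        "u": u,
        "v": v,
        "w": w,
        "cell_means": means,
        "template_cs": float(centroid_size(template.coords)),
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------


def _design_weights(n_hist: tuple[int, int], n_mod: tuple[int, int]):
    """Pooled two-group variance decomposition weights.

    For two groups of sizes (n1, n2) with means at +/- delta along one
    direction, the expected pooled mean-squared deviation is
    ``sigma_e^2 (N-1)/N + 4 n1 n2 / N^2 * delta^2``.
    """
    out = []
    for n1, n2 in (n_hist, n_mod):
        total = n1 + n2
        out.append(((total - 1) / total, 4.0 * n1 * n2 / total**2))
    return out  # [(a_h, w_h), (a_m, w_m)]


def _noise_dims(params: SimulationParams) -> int:
    # symmetric subspace (3 per pair + 2 per midline landmark) minus the
    # 4 symmetry-preserving similarity directions removed by superimposition
    return 3 * params.k_pairs + 2 * params.k_midline - 4


def _simulated_template_cs(params: SimulationParams) -> float:
    """Centroid size of the exact template :func:`simulate_dataset` draws."""
    rng = np.random.default_rng(params.seed)
    template, _ = make_template(
        params.k_pairs, params.k_midline, seed=int(rng.integers(2**31))
    )
    return float(centroid_size(template.coords))


def effective_shape_variance(params: SimulationParams, template_cs: float) -> float:
    """Expected per-specimen squared deviation of the symmetric shape
    component, in unit-centroid-size shape space."""
    return params.noise_sd**2 * _noise_dims(params) / template_cs**2


def expected_mci(params: SimulationParams, template_cs: float | None = None) -> ExpectedMci:
    """Tangent-space approximation of the mean simulated MCI.

    ``MCI ~ (a_h s + w_h d'^2) / (a_m s + w_m ((1-c) d')^2)`` where ``s``
    is the effective shape variance, ``d'`` the lineage offset in shape
    units, and (a, w) the pooled-variance design weights of the historic
    and modern strata. Valid only in the small-noise regime; the
    ``in_regime`` flag is False outside it (or in degenerate limits).
    """
    if template_cs is None:
        template_cs = _simulated_template_cs(params)
    s = effective_shape_variance(params, template_cs)
    delta = params.lineage_offset / template_cs
    delta_m = (1.0 - params.convergence) * delta
    (a_h, w_h), (a_m, w_m) = _design_weights(
        (params.n_per_cell[0], params.n_per_cell[2]),
        (params.n_per_cell[1], params.n_per_cell[3]),
    )
    denom = a_m * s + w_m * delta_m**2
    if denom < 1e-15:
        return ExpectedMci(float("inf"), False)
    value = (a_h * s + w_h * delta**2) / denom
    scale = np.sqrt(3 * params.k) * params.noise_sd / template_cs
    in_regime = delta <= 0.25 and scale <= 0.25 and np.isfinite(value)
    return ExpectedMci(float(value), bool(in_regime))


def calibrate_lineage_offset(
    params: SimulationParams, target_mci: float, template_cs: float | None = None
) -> SimulationParams:
    """Return params with ``lineage_offset`` set so that
    ``expected_mci`` equals ``target_mci`` at the params' convergence."""
    if template_cs is None:
        template_cs = _simulated_template_cs(params)
    s = effective_shape_variance(params, template_cs)
    (a_h, w_h), (a_m, w_m) = _design_weights(
        (params.n_per_cell[0], params.n_per_cell[2]),
        (params.n_per_cell[1], params.n_per_cell[3]),
    )
    shrink = (1.0 - params.convergence) ** 2
    denom = w_h - target_mci * w_m * shrink
    delta_sq = s * (target_mci * a_m - a_h) / denom
    if denom <= 0 or delta_sq <= 0:
        raise ValueError(
            f"target MCI {target_mci} unreachable at convergence "
            f"{params.convergence} with this design"
        )
    return replace(params, lineage_offset=float(np.sqrt(delta_sq) * template_cs))
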