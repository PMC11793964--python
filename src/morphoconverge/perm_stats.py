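"""Permutation ANOVA and pairwise tests via residual randomization (RRPP).

The ANOVA uses Type II sums of squares on a (possibly multivariate)
response: each main effect is adjusted for the other main effects, the
interaction for all main effects. Null distributions come from residual
randomization: for each term, residuals of its reduced model are permuted
and added back to the reduced-model fitted values, and the term's statistic
is recomputed.

Conventions (shared by every test here):

* the observed statistic counts in its own null, so with ``n_perm = 999``
  the smallest attainable p is 0.001;
* p-values are one-sided upper (ties count as >=);
* effect sizes Z are standardized positions in the permutation
  distribution — computed on ln F for ANOVA terms (right-skewed) and on
  the raw statistic for pairwise distances and variance differences, so
  negative Z means the observed value sits below the null mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_REL_TOL = 1e-12  # tie tolerance for >= comparisons in permutation counts


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Rows of a permutation ANOVA (terms + residuals + total)."""

    table: pd.DataFrame
    n_perm: int
    seed: int | None
    ss_type: str = "II"

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AnovaTable(ss_type={self.ss_type}, n_perm={self.n_perm}, "
            f"seed={self.seed})\n{self.table}"
        )


@dataclass
class PairwiseResult:
    """Pairwise mean-distance or variance-difference comparisons."""

    table: pd.DataFrame  # group_a, group_b, statistic, Z, p
    mode: str  # "means" | "variances"
    group_variances: dict = field(default_factory=dict)
    n_perm: int = 999
    seed: int | None = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairwiseResult(mode={self.mode}, n_perm={self.n_perm})\n{self.table}"


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def parse_model(model: str) -> list[tuple[str, ...]]:
    """Parse e.g. ``"period + lineage + period:lineage"`` into term tuples."""
    terms = []
    for chunk in model.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        terms.append(tuple(part.strip() for part in chunk.split(":")))
    if not terms:
        raise DesignError(f"empty model {model!r}")
    return terms


def _levels(values: np.ndarray) -> list:
    return sorted(set(values.tolist()))


def _dummy(values: np.ndarray) -> np.ndarray:
    """Treatment-coded columns (reference level = first sorted level)."""
    levels = _levels(values)
    cols = [(values == lev).astype(float) for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def _term_columns(factors: dict, term: tuple[str, ...]) -> np.ndarray:
    blocks = [_dummy(np.asarray(factors[f], dtype=object)) for f in term]
    out = blocks[0]
    for block in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, block).reshape(len(block), -1)
    return out


def _design_matrix(factors: dict, terms: list[tuple[str, ...]], n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    cols += [_term_columns(factors, t) for t in terms]
    return np.concatenate(cols, axis=1)


def _basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of ``x``."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return u[:, s > tol]


def _check_cells(factors: dict, terms: list[tuple[str, ...]]) -> None:
    for term in terms:
        if len(term) < 2:
            continue
        arrays = [np.asarray(factors[f], dtype=object) for f in term]
        observed = set(zip(*arrays))
        for combo in itertools.product(*[_levels(a) for a in arrays]):
            if combo not in observed:
                cell = ", ".join(f"{f}={v}" for f, v in zip(term, combo))
                raise DesignError(f"design has an empty cell ({cell})")


def _p_and_z(dist: np.ndarray, observed: float, log_scale: bool) -> tuple[float, float]:
    thresh = observed - _REL_TOL * max(1.0, abs(observed))
    p = float(np.mean(dist >= thresh))
    vals = np.log(np.maximum(dist, 1e-300)) if log_scale else dist
    obs = np.log(max(observed, 1e-300)) if log_scale else observed
    sd = float(np.std(vals, ddof=1))
    z = float((obs - vals.mean()) / sd) if sd > 0 else 0.0
    return p, z


def _permutation_matrix(
    n: int, n_perm: int, seed, permutations
) -> tuple[np.ndarray, bool]:
    """Return (perm index matrix, observed_included_in_matrix)."""
    if permutations is not None:
        perms = np.asarray(permutations, dtype=int)
        if perms.ndim != 2 or perms.shape[1] != n:
            raise DesignError(f"permutations must be (m, {n}) index rows")
        return perms, True
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(n) for _ in range(n_perm)]), False


# ---------------------------------------------------------------------------
# permutation ANOVA
# ---------------------------------------------------------------------------


def rrpp_anova(
    response,
    factors: dict,
    model: str = "period + lineage + period:lineage",
    n_perm: int = 999,
    seed: int | None = None,
    permutations=None,
) -> AnovaTable:
    """Type II permutation ANOVA with residual randomization.

    ``response`` is (n,) or (n, q); ``factors`` maps factor names to
    length-n label arrays. ``permutations`` may supply an explicit (m, n)
    matrix of row permutations (e.g. the full enumeration for exact tests);
    when given, p is the proportion of those m statistics >= observed, with
    no extra observed term added (include the identity row for the usual
    convention).
    """
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    terms = parse_model(model)
    for f in {f for t in terms for f in t}:
        if f not in factors:
            raise DesignError(f"model references unknown factor {f!r}")
        if len(np.asarray(factors[f])) != n:
            raise DesignError(f"factor {f!r} length does not match response rows")
    ss_total = float(((y - y.mean(axis=0)) ** 2).sum())
    if ss_total <= 0:
        raise DesignError("constant response: no variation to partition")
    _check_cells(factors, terms)

    x_full = _design_matrix(factors, terms, n)
    b_full = _basis(x_full)
    rank_full = b_full.shape[1]
    if rank_full >= n:
        raise DesignError("saturated design: no residual degrees of freedom")
    df_res = n - rank_full
    ss_res = float((y**2).sum() - ((b_full.T @ y) ** 2).sum())
    ms_res = ss_res / df_res

    perms, explicit = _permutation_matrix(n, n_perm, seed, permutations)

    rows = []
    for term in terms:
        reduced = [t for t in terms if not set(term) <= set(t)]
        b_red = _basis(_design_matrix(factors, reduced, n))
        b_ft = _basis(_design_matrix(factors, reduced + [term], n))
        df_term = b_ft.shape[1] - b_red.shape[1]
        if df_term < 1:
            raise DesignError(f"term {':'.join(term)} adds no degrees of freedom")

        def stats(yy: np.ndarray) -> float:
            ss_t = float(((b_ft.T @ yy) ** 2).sum() - ((b_red.T @ yy) ** 2).sum())
            ss_r = float((yy**2).sum() - ((b_full.T @ yy) ** 2).sum())
            return ss_t, (ss_t / df_term) / (ss_r / df_res) if ss_r > 0 else np.inf

        ss_obs, f_obs = stats(y)
        fitted = b_red @ (b_red.T @ y)
        resid = y - fitted
        f_null = np.empty(perms.shape[0])
        for j, perm in enumerate(perms):
            _, f_null[j] = stats(fitted + resid[perm])
        dist = f_null if explicit else np.concatenate([[f_obs], f_null])
        p, z = _p_and_z(dist, f_obs, log_scale=True)
        rows.append(
            {
                "term": ":".join(term),
                "df": df_term,
                "SS": ss_obs,
                "MS": ss_obs / df_term,
                "R2": ss_obs / ss_total,
                "F": f_obs,
                "Z": z,
                "p": p,
            }
        )
    rows.append(
        {
            "term": "residuals",
            "df": df_res,
            "SS": ss_res,
            "MS": ms_res,
            "R2": ss_res / ss_total,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "total",
            "df": n - 1,
            "SS": ss_total,
            "MS": np.nan,
            "R2": 1.0,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return AnovaTable(table=table, n_perm=perms.shape[0], seed=seed)


# ---------------------------------------------------------------------------
# group helpers
# ---------------------------------------------------------------------------


def _cells(lineage, period) -> tuple[np.ndarray, list[tuple[str, str]]]:
    lineage = np.asarray(lineage, dtype=object)
    period = np.asarray(period, dtype=object)
    labels = np.array(
        [f"{p} {g}" for g, p in zip(lineage, period)], dtype=object
    )
    cells = [
        (g, p)
        for g in _levels(lineage)
        for p in _levels(period)
        if np.any((lineage == g) & (period == p))
    ]
    return labels, cells


def _cell_label(cell: tuple[str, str]) -> str:
    lineage, period = cell
    return f"{period} {lineage}"


def _select_pairs(cells, pairs):
    if pairs == "all":
        return list(itertools.combinations(cells, 2))
    if pairs == "within_lineage":
        out = []
        for g in sorted({c[0] for c in cells}):
            per = [c for c in cells if c[0] == g]
            out += list(itertools.combinations(per, 2))
        return out
    return [tuple(p) for p in pairs]


def procrustes_variance(response, groups) -> dict:
    """Disparity per group: mean squared deviation from the group mean
    (divisor n_g, not n_g - 1)."""
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    groups = np.asarray(groups, dtype=object)
    out = {}
    for level in dict.fromkeys(groups):
        mask = groups == level
        if not mask.any():
            raise DesignError(f"empty group {level!r}")
        block = y[mask]
        out[level] = float(((block - block.mean(axis=0)) ** 2).sum() / block.shape[0])
    return out


# ---------------------------------------------------------------------------
# pairwise tests
# ---------------------------------------------------------------------------


def pairwise_means(
    response,
    lineage,
    period,
    n_perm: int = 999,
    seed: int | None = None,
    pairs="within_lineage",
) -> PairwiseResult:
    """Euclidean distances between least-squares (cell) means with an RRPP
    null under the main-effects-only reduced model.

    The reported distance is between the raw least-squares means. The test
    statistic applies one identical estimator to every arrangement: reduced
    -model residuals are permuted, the permuted data are re-residualized
    against the reduced model, and group-mean contrasts of that residual
    field are compared (the observed arrangement is the identity
    permutation). Re-residualizing keeps the statistic exchangeable under
    the null — carrying the fixed estimated main effects into every
    permuted draw would systematically inflate null distances for
    high-dimensional responses.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    labels, cells = _cells(lineage, period)
    counts = {c: int(np.sum(labels == _cell_label(c))) for c in cells}
    small = [c for c, cnt in counts.items() if cnt < 2]
    if small:
        raise DesignError(f"group(s) with < 2 members: {[_cell_label(c) for c in small]}")
    pair_list = _select_pairs(cells, pairs)

    g_mat = np.stack(
        [(labels == _cell_label(c)).astype(float) / counts[c] for c in cells]
    )  # (g, n) averaging matrix
    cell_index = {c: i for i, c in enumerate(cells)}

    b_red = _basis(
        _design_matrix({"lineage": lineage, "period": period}, [("period",), ("lineage",)], n)
    )
    resid = y - b_red @ (b_red.T @ y)

    means = g_mat @ y
    d_obs = np.array(
        [np.linalg.norm(means[cell_index[a]] - means[cell_index[b]]) for a, b in pair_list]
    )

    def contrast_stats(e: np.ndarray) -> np.ndarray:
        mj = g_mat @ e
        return np.array(
            [
                np.linalg.norm(mj[cell_index[a]] - mj[cell_index[b]])
                for a, b in pair_list
            ]
        )

    s_obs = contrast_stats(resid)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(pair_list)))
    for j in range(n_perm):
        e = resid[rng.permutation(n)]
        null[j] = contrast_stats(e - b_red @ (b_red.T @ e))

    rows = []
    for i, (a, b) in enumerate(pair_list):
        dist = np.concatenate([[s_obs[i]], null[:, i]])
        p, z = _p_and_z(dist, s_obs[i], log_scale=False)
        rows.append(
            {
                "group_a": _cell_label(a),
                "group_b": _cell_label(b),
                "distance": d_obs[i],
                "Z": z,
                "p": p,
            }
        )
    return PairwiseResult(
        table=pd.DataFrame(rows), mode="means", n_perm=n_perm, seed=seed
    )


def pairwise_variances(
    response,
    lineage,
    period,
    n_perm: int = 999,
    seed: int | None = None,
    pairs="within_lineage",
) -> PairwiseResult:
    """Absolute differences in group disparity with a residual-shuffling
    null.

    Disparities are computed from residuals of the cell-means (full) model,
    and the null reassigns those residual magnitudes to groups by permuting
    specimen rows — so mean differences between groups cannot masquerade as
    variance differences.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    labels, cells = _cells(lineage, period)
    counts = {c: int(np.sum(labels == _cell_label(c))) for c in cells}
    small = [c for c, cnt in counts.items() if cnt < 2]
    if small:
        raise DesignError(f"group(s) with < 2 members: {[_cell_label(c) for c in small]}")
    pair_list = _select_pairs(cells, pairs)

    centred = y.copy()
    for c in cells:
        mask = labels == _cell_label(c)
        centred[mask] -= y[mask].mean(axis=0)
    sq = (centred**2).sum(axis=1)  # squared residual distance per specimen

    masks = {c: labels == _cell_label(c) for c in cells}
    pv_obs = {c: float(sq[masks[c]].mean()) for c in cells}
    d_obs = np.array([abs(pv_obs[a] - pv_obs[b]) for a, b in pair_list])

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(pair_list)))
    for j in range(n_perm):
        sq_j = sq[rng.permutation(n)]
        pv_j = {c: sq_j[masks[c]].mean() for c in cells}
        for i, (a, b) in enumerate(pair_list):
            null[j, i] = abs(pv_j[a] - pv_j[b])

    rows = []
    for i, (a, b) in enumerate(pair_list):
        dist = np.concatenate([[d_obs[i]], null[:, i]])
        p, z = _p_and_z(dist, d_obs[i], log_scale=False)
        rows.append(
            {
                "group_a": _cell_label(a),
                "group_b": _cell_label(b),
                "distance": d_obs[i],
                "Z": z,
                "p": p,
            }
        )
    return PairwiseResult(
        table=pd.DataFrame(rows),
        mode="variances",
        group_variances={_cell_label(c): pv_obs[c] for c in cells},
        n_perm=n_perm,
        seed=seed,
    )
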