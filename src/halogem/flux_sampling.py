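"""Uniform sampling of the steady-state flux polytope.

The feasible set {v : S.v = 0, lb <= v <= ub} is a bounded convex polytope
that is rarely full-dimensional in flux coordinates.  Sampling therefore
works in the polytope's intrinsic coordinates: the equality constraints
(mass balances plus any fixed-flux reactions) are reduced to an affine map
v = v0 + N.alpha with N an orthonormal null-space basis, and the bound
constraints become a full-dimensional polytope in alpha.

Two samplers share that projection:

* ``rejection_sample`` — draw alpha uniformly over the polytope's bounding
  box and keep draws whose back-calculated flux vector respects every bound.
  Exact but collapses beyond a handful of dimensions; guarded at <= 6 and
  kept as the small-system reference.
* ``hit_and_run_sample`` — coordinate hit-and-run from a Chebyshev-center
  start (warmup 1000 steps, thinning 10), the production sampler; its
  stationary distribution is uniform on the polytope.

Randomness comes from a counter-based Philox generator so a seed pins the
sample matrix bitwise.  Every returned sample set is validated against
S.v = 0 (1e-6) and the bounds (1e-9) before it leaves the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import linprog

from .network_core import MetabolicModel, build_S

STEADY_STATE_TOL = 1e-6
BOUND_TOL = 1e-9
DEFAULT_N_VALID = 20000


class SamplingError(RuntimeError):
    pass


@dataclass
class Projection:
    """Affine parametrization v = v0 + N.alpha of the equality manifold."""

    v0: np.ndarray  # particular solution, length n
    N: np.ndarray  # n x d orthonormal null-space basis
    reaction_ids: list[str]
    S: np.ndarray  # dense equality matrix actually reduced (for validation)

    @property
    def dimension(self) -> int:
        return self.N.shape[1]

    def to_flux(self, alpha: np.ndarray) -> np.ndarray:
        return self.v0 + alpha @ self.N.T


def project_to_independent_variables(model: MetabolicModel) -> Projection:
    """Reduce S.v = 0 (plus fixed-flux equalities) to independent coordinates.

    The polytope dimension is n - rank(E) where E stacks the stoichiometric
    rows with one pinning row per fixed (lb == ub) reaction.  A
    zero-dimensional result is legal and denotes a point polytope.
    """
    sm = build_S(model)
    S = sm.matrix.toarray()
    n = S.shape[1]
    extra_rows = []
    rhs = [0.0] * S.shape[0]
    for j, r in enumerate(model.reactions):
        if r.lower_bound == r.upper_bound:
            row = np.zeros(n)
            row[j] = 1.0
            extra_rows.append(row)
            rhs.append(r.lower_bound)
    E = np.vstack([S] + extra_rows) if extra_rows else S
    f = np.array(rhs)
    v0, *_ = np.linalg.lstsq(E, f, rcond=None)
    if np.linalg.norm(E @ v0 - f) > 1e-7:
        raise SamplingError("equality constraints are inconsistent (no steady state)")
    N = scipy.linalg.null_space(E)
    return Projection(v0=v0, N=N, reaction_ids=sm.reaction_ids, S=S)


def _model_bounds(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([r.lower_bound for r in model.reactions], dtype=float),
        np.array([r.upper_bound for r in model.reactions], dtype=float),
    )


def _chebyshev_alpha(proj: Projection, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Interior point in alpha coordinates, via the Chebyshev-center LP."""
    N, v0 = proj.N, proj.v0
    d = proj.dimension
    norms = np.linalg.norm(N, axis=1)
    active = norms > 1e-12
    # rows with a zero basis row are fixed coordinates: check feasibility only
    viol = (v0[~active] < lo[~active] - 1e-7) | (v0[~active] > hi[~active] + 1e-7)
    if viol.any():
        raise SamplingError("no feasible point: fixed coordinates violate bounds")
    A_rows, b_rows = [], []
    for i in np.flatnonzero(active):
        # v0_i + N_i.alpha + r*|N_i| <= hi_i  and  -(v0_i + N_i.alpha) + r*|N_i| <= -lo_i
        A_rows.append(np.append(N[i], norms[i]))
        b_rows.append(hi[i] - v0[i])
        A_rows.append(np.append(-N[i], norms[i]))
        b_rows.append(v0[i] - lo[i])
    c = np.zeros(d + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=np.array(A_rows),
        b_ub=np.array(b_rows),
        bounds=[(None, None)] * d + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[-1] < -1e-9:
        raise SamplingError("no feasible interior point for sampling")
    return res.x[:d]


@dataclass
class FluxSampleSet:
    """n_samples x n_reactions matrix of valid steady-state flux vectors."""

    matrix: np.ndarray
    reaction_ids: list[str]
    condition: str
    seed: int
    sampler: str

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.reaction_ids)

    def column(self, rid: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(rid)]

    def validate(self, model: MetabolicModel) -> None:
        sm = build_S(model)
        if sm.reaction_ids != self.reaction_ids:
            raise SamplingError("sample reaction index does not match model")
        resid = np.abs(sm.matrix @ self.matrix.T)
        if resid.size and resid.max() > STEADY_STATE_TOL:
            raise SamplingError(f"steady-state residual {resid.max():.3g} > {STEADY_STATE_TOL}")
        lo, hi = _model_bounds(model)
        if ((self.matrix < lo - BOUND_TOL) | (self.matrix > hi + BOUND_TOL)).any():
            raise SamplingError("sample violates flux bounds beyond tolerance")


def _finish(matrix, model, proj, condition, seed, sampler) -> FluxSampleSet:
    lo, hi = _model_bounds(model)
    matrix = np.clip(matrix, lo, hi)  # shave float-level boundary overshoot
    out = FluxSampleSet(
        matrix=matrix,
        reaction_ids=proj.reaction_ids,
        condition=condition,
        seed=seed,
        sampler=sampler,
    )
    out.validate(model)
    return out


def rejection_sample(
    model: MetabolicModel,
    n: int,
    seed: int,
    condition: str = "",
    max_dim: int = 6,
    min_acceptance: float = 1e-6,
) -> FluxSampleSet:
    """Literal box-rejection sampler; the <=``max_dim``-D reference method.

    Independent coordinates are drawn uniformly over the polytope's bounding
    box; dependent fluxes are back-calculated through the null-space map and
    draws violating any bound are rejected, until ``n`` valid points remain.
    """
    proj = project_to_independent_variables(model)
    d = proj.dimension
    if d > max_dim:
        raise SamplingError(
            f"rejection sampler limited to {max_dim} dimensions, polytope has {d}"
        )
    lo, hi = _model_bounds(model)
    if d == 0:
        v = proj.v0
        if ((v < lo - 1e-7) | (v > hi + 1e-7)).any():
            raise SamplingError("point polytope violates bounds: infeasible model")
        return _finish(np.tile(v, (n, 1)), model, proj, condition, seed, "rejection")

    # bounding box of alpha via 2d LPs on the flux-space constraints
    box_lo, box_hi = np.empty(d), np.empty(d)
    A_ub = np.vstack([proj.N, -proj.N])
    b_ub = np.concatenate([hi - proj.v0, proj.v0 - lo])
    keep = np.isfinite(b_ub)
    for k in range(d):
        c = np.zeros(d)
        c[k] = 1.0
        lo_res = linprog(c, A_ub=A_ub[keep], b_ub=b_ub[keep],
                         bounds=[(None, None)] * d, method="highs")
        hi_res = linprog(-c, A_ub=A_ub[keep], b_ub=b_ub[keep],
                         bounds=[(None, None)] * d, method="highs")
        if not (lo_res.success and hi_res.success):
            raise SamplingError("could not bound the sampling box: infeasible polytope")
        box_lo[k], box_hi[k] = lo_res.x[k], -hi_res.fun

    rng = np.random.Generator(np.random.Philox(seed))
    rows = []
    drawn = 0
    batch = max(4 * n, 1000)
    while sum(len(r) for r in rows) < n:
        alpha = rng.uniform(box_lo, box_hi, size=(batch, d))
        v = proj.to_flux(alpha)
        ok = ((v >= lo - BOUND_TOL) & (v <= hi + BOUND_TOL)).all(axis=1)
        rows.append(v[ok])
        drawn += batch
        accepted = sum(len(r) for r in rows)
        if drawn >= 1e6 and accepted / drawn < min_acceptance:
            raise SamplingError(
                f"acceptance rate {accepted / drawn:.2e} below {min_acceptance}; "
                "polytope too thin for box rejection"
            )
    matrix = np.vstack(rows)[:n]
    return _finish(matrix, model, proj, condition, seed, "rejection")


def hit_and_run_sample(
    model: MetabolicModel,
    n: int,
    seed: int,
    condition: str = "",
    warmup: int = 1000,
    thinning: int = 10,
) -> FluxSampleSet:
    """Coordinate hit-and-run over the projected polytope (production sampler).

    From a Chebyshev-center start, each step picks a random independent
    coordinate, computes the feasible segment along it, and jumps to a
    uniform point on that segment.  The first ``warmup`` steps are discarded
    and every ``thinning``-th step is kept thereafter.
    """
    proj = project_to_independent_variables(model)
    lo, hi = _model_bounds(model)
    d = proj.dimension
    if d == 0:
        v = proj.v0
        if ((v < lo - 1e-7) | (v > hi + 1e-7)).any():
            raise SamplingError("point polytope violates bounds: infeasible model")
        return _finish(np.tile(v, (n, 1)), model, proj, condition, seed, "hit_and_run")

    alpha = _chebyshev_alpha(proj, lo, hi)
    N = proj.N
    w = proj.v0 + N @ alpha  # current flux vector, updated incrementally
    rng = np.random.Generator(np.random.Philox(seed))
    cols = [np.flatnonzero(np.abs(N[:, k]) > 1e-12) for k in range(d)]
    out = np.empty((n, len(proj.reaction_ids)))
    kept = 0
    step = 0
    total_steps = warmup + n * thinning
    while kept < n:
        k = int(rng.integers(d))
        idx = cols[k]
        a = N[idx, k]
        tlo, thi = -np.inf, np.inf
        room_hi = (hi[idx] - w[idx]) / a
        room_lo = (lo[idx] - w[idx]) / a
        pos = a > 0
        thi = min(room_hi[pos].min(initial=np.inf), room_lo[~pos].min(initial=np.inf))
        tlo = max(room_lo[pos].max(initial=-np.inf), room_hi[~pos].max(initial=-np.inf))
        if not np.isfinite(tlo) or not np.isfinite(thi):
            raise SamplingError("unbounded direction encountered; polytope not bounded")
        if thi > tlo:
            t = rng.uniform(tlo, thi)
            w[idx] = w[idx] + a * t
        step += 1
        if step > warmup and (step - warmup) % thinning == 0:
            out[kept] = w
            kept += 1
        if step > total_steps + 10 * thinning * n:  # pragma: no cover - safety
            raise SamplingError("hit-and-run failed to collect enough points")
    return _finish(out, model, proj, condition, seed, "hit_and_run")


def median_fluxes(sample: FluxSampleSet, normalize_by: str) -> pd.Series:
    """Per-reaction sample medians normalized by |median substrate uptake|.

    ``normalize_by`` names the substrate (glucose) exchange; its own
    normalized value is -1 by construction under the uptake-negative
    convention.
    """
    med = pd.Series(np.median(sample.matrix, axis=0), index=sample.reaction_ids)
    g = med[normalize_by]
    if g == 0:
        raise ValueError(f"median flux of {normalize_by!r} is zero; cannot normalize")
    return med / abs(g)
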