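"""Pseudo-first-order master equation of the coarse-grained system.

Under ligand excess the free ligand concentration stays at its initial
value ``l0``, which linearizes the bimolecular association step.  With
monomer basins ``alpha_1..alpha_n`` and complex basins ``beta_1..beta_m``,
the concentration vector ``gamma = (alpha_1..alpha_n, beta_1..beta_m)``
obeys ``d gamma / dt = R(l0) gamma`` with the block generator

    R(l0) = [[ A,        C ],
             [ l0 * D,   B ]]

where ``A``/``B`` hold the intra-world macrorates, ``C`` the dissociation
macrorates, ``D`` the association macrorates, and each diagonal entry is
the negative column sum (so total RNA is conserved exactly).  The equation
is solved in closed form, ``c(t) = exp(t R(l0)) c(0)``, via a
detailed-balance symmetrization and orthogonal eigendecomposition.

Two reference solvers validate the model on small systems: the same
construction on the full microstate space, and a numerical integration of
the true nonlinear bimolecular system with a finite ligand pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .coarse_grain import CoarseGraining, macrorate_matrix
from .errors import InputError, NumericalError
from .landscape import Landscape
from .ligand_coupling import cross_rate_matrices
from .rate_model import RateModel, metropolis

_PI_FLOOR = 1e-300


@dataclass
class RateMatrix:
    """Assembled pseudo-first-order generator and its building blocks.

    ``blocks = (A, B, C, D)`` carry the macrorates with zero diagonals; the
    assembled matrix includes the diagonal drains and the ``l0`` scaling of
    the association block.  ``pi`` is the (unnormalized) Boltzmann
    stationary weight vector ``(Z[alpha_i], l0 e^{-b theta} Z[beta_j])``.
    """

    n: int
    m: int
    l0: float
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    assembled: np.ndarray = field(repr=False)
    pi: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.n + self.m


@dataclass
class Trajectory:
    """Time grid plus macrostate concentration vectors (rows = times)."""

    times: np.ndarray
    concentrations: np.ndarray
    n_monomer: int

    def total(self) -> np.ndarray:
        return self.concentrations.sum(axis=1)

    def bound_fraction(self) -> np.ndarray:
        """Fraction of total RNA in the complex world at each time."""
        return self.concentrations[:, self.n_monomer :].sum(axis=1) / self.total()


def default_time_grid(
    t_min: float = 1e-6, t_max: float = 1e8, points: int = 200
) -> np.ndarray:
    """Logarithmic default output grid (folding spans many decades)."""
    return np.logspace(math.log10(t_min), math.log10(t_max), points)


def _check_generator(R: np.ndarray) -> None:
    off = R - np.diag(np.diag(R))
    if off.min() < 0:
        raise NumericalError("negative off-diagonal rate in assembled generator")
    col = R.sum(axis=0)
    scale = max(np.abs(R).max(), 1.0)
    if np.abs(col).max() > 1e-12 * scale:
        raise NumericalError("generator column sums deviate from zero")


def assemble(
    monomer_cg: CoarseGraining,
    dimer_cg: CoarseGraining | None,
    cross_rates: tuple[np.ndarray, np.ndarray] | None,
    rate_model: RateModel,
    l0: float,
    *,
    intra_rates: tuple[np.ndarray, np.ndarray | None] | None = None,
) -> RateMatrix:
    """Assemble the block generator ``R(l0)``.

    ``cross_rates`` is the pair ``(assoc, dissoc)`` from
    :func:`rlkin.ligand_coupling.cross_rate_matrices`; ``intra_rates`` may
    carry precomputed intra-world macrorate matrices.  Passing precomputed
    rates lets an ``l0`` (or prefactor) sweep skip the expensive landscape
    work: only this assembly depends on ``l0``.
    """
    if l0 < 0:
        raise InputError("ligand concentration must be non-negative")
    n = len(monomer_cg)
    m = len(dimer_cg) if dimer_cg is not None else 0

    if intra_rates is not None:
        mono_rates, dimer_rates = intra_rates
    else:
        mono_rates = macrorate_matrix(monomer_cg, rate_model)
        dimer_rates = macrorate_matrix(dimer_cg, rate_model) if m else None

    # blocks store targets in rows: A[i, j] = r(alpha_i <- alpha_j)
    A = mono_rates.T.copy()
    np.fill_diagonal(A, 0.0)
    if m:
        B = dimer_rates.T.copy()
        np.fill_diagonal(B, 0.0)
        if cross_rates is None:
            cross_rates = cross_rate_matrices(monomer_cg, dimer_cg, rate_model)
        assoc, dissoc = cross_rates
        D = np.asarray(assoc, dtype=float)  # D[j, i] = r(beta_j <- alpha_i)
        C = np.asarray(dissoc, dtype=float)  # C[i, j] = r(alpha_i <- beta_j)
        if D.shape != (m, n) or C.shape != (n, m):
            raise InputError("cross-rate matrices have inconsistent shapes")
    else:
        B = np.zeros((0, 0))
        C = np.zeros((n, 0))
        D = np.zeros((0, n))

    R = np.zeros((n + m, n + m))
    R[:n, :n] = A
    R[:n, n:] = C
    R[n:, :n] = l0 * D
    R[n:, n:] = B
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=0))
    _check_generator(R)

    b = rate_model.beta
    pi = np.empty(n + m)
    pi[:n] = [ms.Z for ms in monomer_cg.macrostates]
    if m:
        pi[n:] = l0 * math.exp(-b * rate_model.theta) * np.array(
            [ms.Z for ms in dimer_cg.macrostates]
        )
    return RateMatrix(n=n, m=m, l0=l0, A=A, B=B, C=C, D=D, assembled=R, pi=pi)


# ---------------------------------------------------------------------------
# closed-form propagation
# ---------------------------------------------------------------------------


def _symmetrized_eig(R: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of ``diag(pi)^{-1/2} R diag(pi)^{1/2}``.

    Returns ``None`` when the transform is not symmetric (detailed balance
    violated or unusable ``pi``), signalling the caller to fall back.
    """
    if np.any(~np.isfinite(pi)) or np.any(pi <= 0):
        return None
    if pi.min() < _PI_FLOOR:
        warnings.warn("stationary weights below 1e-300 floored", stacklevel=2)
        pi = np.maximum(pi, _PI_FLOOR)
    s = np.sqrt(pi / pi.max())
    M = (R * s[None, :]) / s[:, None]
    scale = max(np.abs(M).max(), 1.0)
    if np.abs(M - M.T).max() > 1e-8 * scale:
        return None
    w, U = np.linalg.eigh(0.5 * (M + M.T))
    if not np.all(np.isfinite(w)):
        return None
    # sqrt(pi) is the exact null vector of the symmetrized generator; pin
    # the eigenvalue of the best-aligned mode to zero (otherwise its O(eps)
    # perturbation is exponentiated over many decades of time) and clamp
    # spurious positive eigenvalues
    v0 = s / np.linalg.norm(s)
    w[int(np.argmax(np.abs(U.T @ v0)))] = 0.0
    w = np.minimum(w, 0.0)
    return w, U, s


def propagate(Rm: RateMatrix, c0: np.ndarray, times: np.ndarray) -> Trajectory:
    """Solve ``c(t) = exp(t R(l0)) c(0)`` on the given time grid.

    Uses the detailed-balance symmetrization (similarity transform with
    ``diag(pi)^{1/2}``) and an orthogonal eigendecomposition; falls back to
    scaling-and-squaring matrix exponentials when the symmetrized matrix is
    not numerically symmetric (e.g. at ``l0 = 0``, where the complex world
    only drains).
    """
    c0 = np.asarray(c0, dtype=float)
    times = np.asarray(times, dtype=float)
    if c0.shape != (Rm.size,) or c0.min() < 0 or c0.sum() <= 0:
        raise InputError("c0 must be a non-negative vector with positive total")

    R = Rm.assembled
    decomp = _symmetrized_eig(R, Rm.pi)
    if decomp is not None:
        w, U, s = decomp
        y0 = U.T @ (c0 / s)
        conc = np.empty((times.size, Rm.size))
        for k, t in enumerate(times):
            conc[k] = s * (U @ (np.exp(w * t) * y0))
    else:
        conc = np.empty((times.size, Rm.size))
        order = np.argsort(times)
        expm_cache = {}
        for k in order:
            t = float(times[k])
            if t not in expm_cache:
                expm_cache[t] = scipy.linalg.expm(R * t)
            conc[k] = expm_cache[t] @ c0

    if not np.all(np.isfinite(conc)):
        raise NumericalError("non-finite concentrations in propagation")
    total = c0.sum()
    if conc.min() < -1e-7 * total:
        raise NumericalError("strongly negative concentration in propagation")
    conc = np.clip(conc, 0.0, None)
    # total mass is conserved analytically (zero column sums); remove the
    # eigensolver round-off in the conserved quantity, failing loudly if the
    # defect is larger than round-off can explain
    row_tot = conc.sum(axis=1)
    if np.abs(row_tot - total).max() > 1e-6 * total:
        raise NumericalError("mass-conservation defect exceeds round-off scale")
    conc *= (total / row_tot)[:, None]
    return Trajectory(times=times, concentrations=conc, n_monomer=Rm.n)


def stationary(Rm: RateMatrix, total: float = 1.0) -> np.ndarray:
    """Long-time limit of the master equation, normalized to ``total``.

    Computed as the null space of the generator.  For a reducible generator
    (more than one connected component) a warning is issued and the result
    is composed per component, each component weighted by its share of the
    Boltzmann weight.
    """
    R = Rm.assembled
    pattern = (np.abs(R) + np.abs(R.T)) > 0
    np.fill_diagonal(pattern, False)
    ncomp, labels = connected_components(pattern, directed=False)
    if ncomp > 1:
        warnings.warn(
            f"generator is reducible ({ncomp} components); "
            "stationary vector composed per component",
            stacklevel=2,
        )
    out = np.zeros(Rm.size)
    pi_total = Rm.pi.sum()
    for comp in range(ncomp):
        idx = np.flatnonzero(labels == comp)
        sub = R[np.ix_(idx, idx)]
        v = _gth_stationary(sub)
        if v is None:
            ns = scipy.linalg.null_space(sub, rcond=1e-12)
            if ns.shape[1] != 1:
                raise NumericalError(
                    f"expected a one-dimensional null space per component, "
                    f"got {ns.shape[1]}"
                )
            v = ns[:, 0]
            v = np.abs(v) if (v <= 0).all() else np.clip(v, 0.0, None)
        mass = Rm.pi[idx].sum() / pi_total if pi_total > 0 else len(idx) / Rm.size
        out[idx] = v / v.sum() * mass
    return out / out.sum() * total


def _gth_stationary(R: np.ndarray) -> np.ndarray | None:
    """Stationary vector of one generator component by GTH elimination.

    ``R[i, j]`` is the rate j -> i.  The Grassmann-Taksar-Heyman scheme
    uses no subtractions, so every entry of the result carries full
    relative precision even for stiff generators whose rates span many
    orders of magnitude.  Returns ``None`` if an elimination pivot
    vanishes (caller falls back to a null-space solve).
    """
    n = R.shape[0]
    if n == 1:
        return np.ones(1)
    W = R.T.copy()  # W[i, j] = rate i -> j
    np.fill_diagonal(W, 0.0)
    S = np.empty(n)
    for k in range(n - 1, 0, -1):
        s = W[k, :k].sum()
        if not (s > 0):
            return None
        S[k] = s
        W[:k, :k] += np.outer(W[:k, k], W[k, :k]) / s
    pi = np.zeros(n)
    pi[0] = 1.0
    for k in range(1, n):
        pi[k] = (pi[:k] @ W[:k, k]) / S[k]
    total = pi.sum()
    if not np.isfinite(total) or total <= 0:
        return None
    return pi / total


# ---------------------------------------------------------------------------
# microstate-level reference solvers
# ---------------------------------------------------------------------------


def _micro_index(monomer_landscape: Landscape, dimer_world: Landscape):
    mono = list(monomer_landscape.states)
    dim = list(dimer_world.states)
    mono_pos = {x: i for i, x in enumerate(mono)}
    for x in dim:
        if x not in mono_pos:
            raise InputError(
                "microstate reference solvers require the complex world to be "
                "a subset of the monomer landscape"
            )
    return mono, dim, mono_pos


def micro_generator(
    monomer_landscape: Landscape,
    dimer_world: Landscape,
    rate_model: RateModel,
    l0: float,
    *,
    max_states: int = 2000,
) -> RateMatrix:
    """The pseudo-first-order generator on the full microstate space.

    Identical construction to :func:`assemble` but with every microstate as
    its own state — i.e. the coarse graining taken to be the identity.
    Intended as an exact reference for small systems (``<= max_states``).
    """
    mono, dim, mono_pos = _micro_index(monomer_landscape, dimer_world)
    N, M = len(mono), len(dim)
    if N + M > max_states:
        raise InputError(f"microstate system too large ({N + M} > {max_states})")
    b = rate_model.beta
    R = np.zeros((N + M, N + M))
    for i, x in enumerate(mono):
        ex = monomer_landscape.energy(x)
        for y in monomer_landscape.neighbors(x):
            R[mono_pos[y], i] = metropolis(
                ex, monomer_landscape.energy(y), rate_model.A_R, b
            )
    dim_pos = {x: N + j for j, x in enumerate(dim)}
    for j, x in enumerate(dim):
        ex = dimer_world.energy(x)
        for y in dimer_world.neighbors(x):
            R[dim_pos[y], N + j] = metropolis(ex, dimer_world.energy(y), rate_model.A_R, b)
        R[N + j, mono_pos[x]] = l0 * rate_model.A_a
        R[mono_pos[x], N + j] = rate_model.A_d * math.exp(b * rate_model.theta)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=0))
    _check_generator(R)

    pi = np.empty(N + M)
    pi[:N] = [math.exp(-b * monomer_landscape.energy(x)) for x in mono]
    pi[N:] = [
        l0 * math.exp(-b * (dimer_world.energy(x) + rate_model.theta)) for x in dim
    ]
    blocks = (
        R[:N, :N].copy(),
        R[N:, N:].copy(),
        R[:N, N:].copy(),
        R[N:, :N] / l0 if l0 > 0 else R[N:, :N].copy(),
    )
    return RateMatrix(
        n=N, m=M, l0=l0, A=blocks[0], B=blocks[1], C=blocks[2], D=blocks[3],
        assembled=R, pi=pi,
    )


def propagate_micro(
    monomer_landscape: Landscape,
    dimer_world: Landscape,
    rate_model: RateModel,
    l0: float,
    c0: np.ndarray,
    times: np.ndarray,
) -> Trajectory:
    """Exact pseudo-first-order dynamics on the full microstate space."""
    Rm = micro_generator(monomer_landscape, dimer_world, rate_model, l0)
    return propagate(Rm, c0, times)


def micro_basin_marginals(
    traj: Trajectory,
    monomer_landscape: Landscape,
    dimer_world: Landscape,
    monomer_cg: CoarseGraining,
    dimer_cg: CoarseGraining,
) -> np.ndarray:
    """Sum a microstate trajectory over basins, yielding macro coordinates."""
    mono, dim, _ = _micro_index(monomer_landscape, dimer_world)
    n, m = len(monomer_cg), len(dimer_cg)
    out = np.zeros((traj.times.size, n + m))
    for i, x in enumerate(mono):
        out[:, monomer_cg.assignment[x]] += traj.concentrations[:, i]
    for j, x in enumerate(dim):
        out[:, n + dimer_cg.assignment[x]] += traj.concentrations[:, len(mono) + j]
    return out


def propagate_bimolecular(
    monomer_landscape: Landscape,
    dimer_world: Landscape,
    rate_model: RateModel,
    ligand_total: float,
    c0: np.ndarray,
    times: np.ndarray,
    *,
    rtol: float = 1e-10,
    atol_factor: float = 1e-14,
) -> tuple[Trajectory, np.ndarray]:
    """Integrate the true second-order system with a finite ligand pool.

    The free ligand concentration ``[L](t)`` is a dynamic variable consumed
    by association and released by dissociation; everything else matches the
    microstate pseudo-first-order construction.  Returns the microstate
    trajectory and ``[L](t)``.  This is the reference that quantifies the
    quality of the ligand-excess approximation.
    """
    mono, dim, mono_pos = _micro_index(monomer_landscape, dimer_world)
    N, M = len(mono), len(dim)
    c0 = np.asarray(c0, dtype=float)
    if c0.shape != (N + M,):
        raise InputError("c0 has wrong length for the microstate system")

    K = micro_generator(monomer_landscape, dimer_world, rate_model, 0.0).assembled
    # at l0 = 0 the assembled generator contains conformational moves and
    # dissociation but no association; add the bilinear association terms
    k_diss = rate_model.A_d * math.exp(rate_model.beta * rate_model.theta)
    partner = np.array([mono_pos[x] for x in dim], dtype=int)

    def rhs(_t, y):
        c, L = y[:-1], y[-1]
        dc = K @ c
        assoc = rate_model.A_a * L * c[partner]
        dc_assoc = np.zeros_like(c)
        np.subtract.at(dc_assoc, partner, assoc)
        dc_assoc[N:] += assoc
        dc += dc_assoc
        dL = float(k_diss * c[N:].sum() - assoc.sum())
        return np.append(dc, dL)

    total = c0.sum()
    sol = scipy.integrate.solve_ivp(
        rhs,
        (0.0, float(times.max())),
        np.append(c0, ligand_total),
        method="BDF",
        t_eval=np.asarray(times, dtype=float),
        rtol=rtol,
        atol=max(total, ligand_total) * atol_factor,
    )
    if not sol.success:
        raise NumericalError(f"bimolecular integration failed: {sol.message}")
    conc = np.clip(sol.y[:-1].T, 0.0, None)
    return Trajectory(times=sol.t, concentrations=conc, n_monomer=N), sol.y[-1]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def write_rate_matrix(path: str, Rm: RateMatrix, labels: list[str] | None = None) -> None:
    """Sparse triplet TSV ``from_id  to_id  rate`` of the assembled generator
    (off-diagonal entries only), with a header comment recording l0."""
    R = Rm.assembled
    with open(path, "w") as fh:
        fh.write(f"# l0 {Rm.l0:.6e}  n {Rm.n}  m {Rm.m}\n")
        for j in range(Rm.size):
            for i in range(Rm.size):
                if i != j and R[i, j] != 0.0:
                    fh.write(f"{j}\t{i}\t{R[i, j]:.12e}\n")


def read_rate_matrix(path: str) -> tuple[np.ndarray, float, int, int]:
    """Read the triplet TSV back: (assembled matrix, l0, n, m)."""
    l0, n, m = 0.0, 0, 0
    triplets = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                fields = ln[1:].split()
                l0, n, m = float(fields[1]), int(fields[3]), int(fields[5])
                continue
            j, i, r = ln.split()
            triplets.append((int(j), int(i), float(r)))
    R = np.zeros((n + m, n + m))
    for j, i, r in triplets:
        R[i, j] = r
    np.fill_diagonal(R, -R.sum(axis=0))
    return R, l0, n, m


def write_trajectory(path: str, traj: Trajectory, header: str = "") -> None:
    """Trajectory table: '#' comment lines, then ``t c_1 ... c_{n+m}`` rows."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# n_monomer {traj.n_monomer}\n")
        for t, row in zip(traj.times, traj.concentrations):
            fh.write(f"{t:.8e} " + " ".join(f"{c:.8e}" for c in row) + "\n")


def read_trajectory(path: str) -> Trajectory:
    times, rows, n_mono = [], [], 0
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                fields = ln[1:].split()
                if fields[:1] == ["n_monomer"]:
                    n_mono = int(fields[1])
                continue
            vals = [float(v) for v in ln.split()]
            times.append(vals[0])
            rows.append(vals[1:])
    return Trajectory(np.array(times), np.array(rows), n_mono)


def plot_trajectory(traj: Trajectory, labels: list[str] | None = None, ax=None):
    """Minimal log-time trajectory plot; returns the matplotlib axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for k in range(traj.concentrations.shape[1]):
        label = labels[k] if labels else f"state {k}"
        ax.plot(traj.times, traj.concentrations[:, k], label=label)
    ax.set_xscale("log")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("concentration [M]")
    ax.legend(fontsize=7)
    return ax
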