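"""Free-energy estimators for multistate alchemical sampling.

All estimators operate on *reduced* (dimensionless) potentials, u = U/kT,
and return dimensionless free energies; conversion to kJ/mol happens only
at the reporting layer (:meth:`FreeEnergySet.to_kjmol`).

The workhorse is MBAR, the multistate Bennett acceptance ratio, solved
from its self-consistency equations

    f_i = -ln sum_n exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n))

by minimising the equivalent convex objective and polishing with
self-consistent iteration.  Exponential averaging (EXP) and the two-state
Bennett acceptance ratio (BAR) are provided as cross-validation baselines.

No decorrelation or subsampling of time series is performed: samples are
taken as given, and the reported asymptotic uncertainties assume they are
independent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

__all__ = [
    "ReducedPotentialSet",
    "FreeEnergySet",
    "OverlapReport",
    "ConvergenceError",
    "mbar_solve",
    "mbar_uncertainty",
    "exp_estimate",
    "bar_estimate",
    "overlap_matrix",
    "pi_bias_measure",
    "overlap_report",
]

#: molar gas constant in kJ/(mol K)
GAS_CONSTANT_KJ = 8.31446261815324e-3


class ConvergenceError(RuntimeError):
    """Raised when an iterative estimator fails to reach tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclasses.dataclass(frozen=True)
class ReducedPotentialSet:
    """Samples-by-states matrix of reduced potentials.

    Parameters
    ----------
    u_kn
        Array of shape (K, N): reduced potential of sample n evaluated at
        state k.  Samples are concatenated state by state: the first N_0
        columns were drawn from state 0, the next N_1 from state 1, etc.
    n_k
        Number of samples drawn from each state (length K).  States with
        zero samples are allowed as evaluation-only states.
    lambdas
        Optional coupling-parameter schedule, strictly increasing in [0, 1].
    """

    u_kn: np.ndarray
    n_k: np.ndarray
    lambdas: np.ndarray | None = None

    def __post_init__(self):
        u = np.asarray(self.u_kn, dtype=float)
        n = np.asarray(self.n_k, dtype=np.int64)
        object.__setattr__(self, "u_kn", u)
        object.__setattr__(self, "n_k", n)
        if u.ndim != 2:
            raise ValueError("u_kn must be a 2-D (states x samples) array")
        if not np.all(np.isfinite(u)):
            raise ValueError("reduced potentials must be finite")
        if n.shape != (u.shape[0],):
            raise ValueError("n_k must have one entry per state")
        if np.any(n < 0):
            raise ValueError("sample counts must be non-negative")
        if int(n.sum()) != u.shape[1]:
            raise ValueError(
                f"sum of n_k ({int(n.sum())}) must equal the sample count "
                f"({u.shape[1]})"
            )
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=float)
            object.__setattr__(self, "lambdas", lam)
            if lam.shape != (u.shape[0],):
                raise ValueError("lambda schedule must have one value per state")
            if np.any(np.diff(lam) <= 0):
                raise ValueError("lambda schedule must be strictly increasing")
            if lam.min() < 0 or lam.max() > 1:
                raise ValueError("lambda values must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]

    @property
    def n_samples(self) -> int:
        return self.u_kn.shape[1]

    def sample_slice(self, state: int) -> slice:
        """Column slice of the samples drawn from ``state``."""
        start = int(self.n_k[:state].sum())
        return slice(start, start + int(self.n_k[state]))


@dataclasses.dataclass(frozen=True)
class FreeEnergySet:
    """Per-state dimensionless free energies with asymptotic covariance.

    ``f_k`` is anchored at ``f_k[0] == 0``.  ``covariance[i, j]`` is the
    asymptotic covariance of (f_i, f_j) relative to the anchor, so the
    variance of a difference f_i - f_j is ``C_ii + C_jj - 2 C_ij``.
    """

    f_k: np.ndarray
    covariance: np.ndarray
    temperature: float = 300.0

    def __post_init__(self):
        f = np.asarray(self.f_k, dtype=float)
        c = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "f_k", f)
        object.__setattr__(self, "covariance", c)
        if abs(f[0]) > 1e-12:
            raise ValueError("free energies must be anchored at f_0 = 0")
        if c.shape != (f.size, f.size):
            raise ValueError("covariance must be K x K")

    @property
    def kt_kjmol(self) -> float:
        return GAS_CONSTANT_KJ * self.temperature

    def delta_f(self, i: int = 0, j: int = -1) -> float:
        """Dimensionless free-energy difference f_j - f_i."""
        return float(self.f_k[j] - self.f_k[i])

    def delta_f_sigma(self, i: int = 0, j: int = -1) -> float:
        """Asymptotic standard error of f_j - f_i (dimensionless)."""
        c = self.covariance
        var = c[i, i] + c[j, j] - 2.0 * c[i, j]
        return float(np.sqrt(max(var, 0.0)))

    def to_kjmol(self, i: int = 0, j: int = -1) -> tuple[float, float]:
        """(Δf, σ) between states i and j in kJ/mol at ``temperature``."""
        kt = self.kt_kjmol
        return self.delta_f(i, j) * kt, self.delta_f_sigma(i, j) * kt


@dataclasses.dataclass(frozen=True)
class OverlapReport:
    """Phase-space-overlap diagnostics for a multistate data set."""

    matrix: np.ndarray
    pi_values: np.ndarray  # one per adjacent state pair
    adequate: np.ndarray  # Π >= 0.5 per adjacent pair

    @property
    def recommendations(self) -> list[str]:
        """Human-readable λ-insertion recommendations for failing pairs."""
        out = []
        for i, ok in enumerate(self.adequate):
            if not ok:
                out.append(
                    f"overlap between states {i} and {i + 1} is inadequate "
                    f"(Pi = {self.pi_values[i]:.3f} < 0.5): insert an "
                    f"intermediate lambda between them"
                )
        return out


def _log_denominator(u_kn: np.ndarray, f_k: np.ndarray, n_k: np.ndarray) -> np.ndarray:
    """log sum_k N_k exp(f_k - u_kn) per sample, skipping empty states."""
    sampled = n_k > 0
    log_n = np.log(n_k[sampled])
    return logsumexp(
        (f_k[sampled] - u_kn[sampled].T) + log_n, axis=1
    )


def _mbar_weights(data: ReducedPotentialSet, f_k: np.ndarray) -> np.ndarray:
    """N x K matrix W with W[n, k] = exp(f_k - u_kn) / sum_l N_l exp(f_l - u_ln).

    Columns of sampled states satisfy sum_n W[n, k] = 1 at convergence, and
    sum_k N_k W[n, k] = 1 exactly for every sample.
    """
    log_denom = _log_denominator(data.u_kn, f_k, data.n_k)
    return np.exp(f_k[:, None] - data.u_kn - log_denom[None, :]).T


def mbar_solve(
    data: ReducedPotentialSet,
    tolerance: float = 1e-8,
    max_iterations: int = 10_000,
    temperature: float = 300.0,
) -> FreeEnergySet:
    """Solve the MBAR self-consistency equations.

    A convex-objective quasi-Newton minimisation provides the initial
    solution, which is then polished by self-consistent iteration until the
    maximum change of any free energy per sweep is below ``tolerance``.

    Raises
    ------
    ConvergenceError
        If the residual is still above tolerance after ``max_iterations``
        self-consistent sweeps.
    """
    u_kn, n_k = data.u_kn, data.n_k
    k_states = data.n_states
    if np.all(n_k == 0):
        raise ValueError("at least one state must contain samples")
    sampled = np.flatnonzero(n_k > 0)

    # Convex MBAR objective on the sampled states (anchor: first sampled state).
    def objective_and_grad(x: np.ndarray):
        f = np.zeros(k_states)
        f[sampled[1:]] = x
        log_denom = _log_denominator(u_kn, f, n_k)
        obj = log_denom.sum() - float(n_k[sampled] @ f[sampled])
        w = np.exp(f[sampled[1:], None] - u_kn[sampled[1:]] - log_denom[None, :])
        grad = n_k[sampled[1:]] * (w.sum(axis=1) - 1.0)
        return obj, grad

    x0 = np.zeros(len(sampled) - 1)
    if x0.size:
        res = minimize(objective_and_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        x = res.x
    else:
        x = x0
    f_k = np.zeros(k_states)
    f_k[sampled[1:]] = x

    # Self-consistent polishing; also fills in evaluation-only states.
    residual = np.inf
    for _ in range(max_iterations):
        log_denom = _log_denominator(u_kn, f_k, n_k)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f_k)))
        f_k = f_new
        if residual <= tolerance:
            break
    else:
        raise ConvergenceError(
            f"MBAR did not converge in {max_iterations} iterations "
            f"(residual {residual:.3e} > tolerance {tolerance:.3e})",
            residual=residual,
        )

    cov = mbar_uncertainty(data, f_k)
    return FreeEnergySet(f_k=f_k, covariance=cov, temperature=temperature)


def mbar_uncertainty(
    data: ReducedPotentialSet, f_k: np.ndarray | FreeEnergySet
) -> np.ndarray:
    """Asymptotic covariance matrix of the MBAR free energies.

    Uses the singular-value decomposition form of the estimator covariance:
    with W the N x K weight matrix and N = diag(N_k),

        Theta = V S (I - S V' N V S)^+ S V'   where  W = U S V'.

    The returned matrix is re-anchored so that state 0 has zero variance,
    i.e. entry (i, j) is Cov(f_i - f_0, f_j - f_0).
    """
    if isinstance(f_k, FreeEnergySet):
        f_k = f_k.f_k
    w = _mbar_weights(data, np.asarray(f_k, dtype=float))
    col_sums = w.sum(axis=0)
    empty = (data.n_k > 0) & (col_sums < 1e-10)
    if np.any(empty):
        raise ValueError(
            f"state {int(np.flatnonzero(empty)[0])} has zero effective samples"
        )
    _, s, vt = np.linalg.svd(w, full_matrices=False)
    v = vt.T
    inner = np.eye(len(s)) - (s[:, None] * vt) @ (data.n_k[:, None] * v) * s[None, :]
    theta = (v * s) @ np.linalg.pinv(inner, rcond=1e-12) @ (s[:, None] * vt)
    # re-anchor at state 0: Cov(f_i - f_0, f_j - f_0)
    anchored = theta - theta[0, :][None, :] - theta[:, 0][:, None] + theta[0, 0]
    return anchored


def exp_estimate(work: np.ndarray) -> float:
    """Exponential (Zwanzig) averaging: Δf = -ln <exp(-w)>.

    Computed through log-sum-exp, so arbitrarily large work values cannot
    overflow.
    """
    w = np.asarray(work, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("exp_estimate requires at least one work sample")
    if not np.all(np.isfinite(w)):
        raise ValueError("work samples must be finite")
    return float(-(logsumexp(-w) - np.log(w.size)))


def bar_estimate(
    forward: np.ndarray,
    reverse: np.ndarray,
    tolerance: float = 1e-10,
    max_iterations: int = 500,
) -> float:
    """Bennett acceptance ratio from bidirectional work samples.

    ``forward`` holds reduced works w = u_1(x) - u_0(x) for samples from
    state 0; ``reverse`` holds u_0(x) - u_1(x) for samples from state 1.
    Solves the implicit Fermi-function equation for Δf by bracketed root
    finding (the equation is strictly monotone in Δf).
    """
    wf = np.asarray(forward, dtype=float).ravel()
    wr = np.asarray(reverse, dtype=float).ravel()
    if wf.size == 0 or wr.size == 0:
        raise ValueError("both work directions must be non-empty")
    m = np.log(wf.size / wr.size)

    def fermi_balance(df: float) -> float:
        lf = -np.logaddexp(0.0, m + wf - df)  # log 1/(1+exp(M + wf - df))
        lr = -np.logaddexp(0.0, -m + wr + df)
        return logsumexp(lf) - logsumexp(lr)

    lo = min(exp_estimate(wf), -exp_estimate(wr)) - 10.0
    hi = max(exp_estimate(wf), -exp_estimate(wr)) + 10.0
    for _ in range(max_iterations):
        if fermi_balance(lo) * fermi_balance(hi) <= 0:
            return float(brentq(fermi_balance, lo, hi, xtol=tolerance))
        lo -= 10.0
        hi += 10.0
    raise ConvergenceError("BAR root bracketing failed")


def overlap_matrix(
    data: ReducedPotentialSet, f: FreeEnergySet | np.ndarray
) -> np.ndarray:
    """Row-stochastic K x K matrix of expected sampling weights.

    Entry (i, j) estimates the probability that a sample from state i would
    be attributed to state j under the mixture distribution:
    O_ij = sum_n W_ni N_j W_nj.  Rows sum to one; for identical states every
    entry is 1/K (for equal sample counts).
    """
    f_k = f.f_k if isinstance(f, FreeEnergySet) else np.asarray(f, dtype=float)
    w = _mbar_weights(data, f_k)
    return w.T @ (w * data.n_k[None, :])


def _relative_entropy(data: ReducedPotentialSet, f_k: np.ndarray, i: int, j: int) -> float:
    """KL divergence s = D(p_i || p_j) estimated from the samples of state i.

    With p_k ∝ exp(-u_k), s = (f_i - f_j) + <u_j - u_i>_i >= 0.
    """
    cols = data.sample_slice(i)
    du = data.u_kn[j, cols] - data.u_kn[i, cols]
    return float((f_k[i] - f_k[j]) + du.mean())


def pi_bias_measure(
    data: ReducedPotentialSet,
    pair: tuple[int, int],
    f: FreeEnergySet | np.ndarray | None = None,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Wu-Kofke-style overlap/bias measure Π for one pair of states.

    For each sampling direction the measure compares the information
    available in the sample (sqrt(2 ln N)) with the information needed to
    bridge the two distributions (sqrt(2 s), where s is the relative
    entropy between the states; for Gaussian work distributions
    sqrt(2 s) equals the work standard deviation):

        Π_dir = sqrt(2 ln N_sampling) - sqrt(2 s_dir)

    and the reported Π is the minimum over the two directions.  Sampling is
    adequate when Π >= ``threshold`` (default 0.5, the boundary itself
    passing); an inadequate flag is a recommendation to insert a λ midpoint
    between the states.

    Returns
    -------
    (pi, adequate)
    """
    i, j = pair
    n_i, n_j = int(data.n_k[i]), int(data.n_k[j])
    if n_i < 10 or n_j < 10:
        raise ValueError(
            "Pi bias measure requires at least 10 samples in each state "
            f"(got N_{i}={n_i}, N_{j}={n_j})"
        )
    if f is None:
        f = mbar_solve(data)
    f_k = f.f_k if isinstance(f, FreeEnergySet) else np.asarray(f, dtype=float)
    pi_fwd = np.sqrt(2.0 * np.log(n_i)) - np.sqrt(
        2.0 * max(_relative_entropy(data, f_k, i, j), 0.0)
    )
    pi_rev = np.sqrt(2.0 * np.log(n_j)) - np.sqrt(
        2.0 * max(_relative_entropy(data, f_k, j, i), 0.0)
    )
    pi = float(min(pi_fwd, pi_rev))
    return pi, pi >= threshold


def overlap_report(
    data: ReducedPotentialSet, f: FreeEnergySet | None = None
) -> OverlapReport:
    """Full overlap diagnostics: matrix plus per-adjacent-pair Π values."""
    if f is None:
        f = mbar_solve(data)
    mat = overlap_matrix(data, f)
    pis, flags = [], []
    for i in range(data.n_states - 1):
        pi, ok = pi_bias_measure(data, (i, i + 1), f)
        pis.append(pi)
        flags.append(ok)
    return OverlapReport(
        matrix=mat, pi_values=np.array(pis), adequate=np.array(flags, dtype=bool)
    )
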