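"""Moment-matching inference of the landscape's mean parameters.

The landscape's first/second-order marginals are estimated by matching the
moment-propagated trajectory to the observed per-round codon frequencies.
The marginals are reparameterized at the amino-acid level through softmaxes

    nu_i(a)    = softmax(gamma_i)(a)
    mu_i(c)    = nu_i(AC(c)) / sum_c' nu_i(AC(c'))        (synonymous codons
                                                           share mass)

(and the pairwise analogue), which enforces normalization by construction.
The fitted objective is the aggregated cross-entropy between observed and
propagated frequencies over the sequenced rounds, plus l2 penalties on gamma
and a quadratic local-consistency penalty tying the single-site marginals to
the pair marginals.  Exact global consistency of the mean vector is a hard
marginal-polytope constraint and is intentionally relaxed to this penalty.

Gradients are computed by hand-written reverse-mode differentiation through
the moment recursion (the graph decomposes per position and per pair), and
optimized with a deterministic Adam loop with early stopping.  Canonical
Potts parameters are then obtained by mean-field inversion of the connected
correlation matrix in a reference-state (wild-type) gauge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .moments import EmpiricalFrequencies, aggregate_to_amino_acids
from .mutation import MutationModel
from .potts import PottsModel, pair_indices
from .seqcore import ALPHABET, CodonSequence


@dataclass
class GammaParams:
    """Unconstrained amino-acid-level parameters of the mean-value model."""

    first: np.ndarray  # (L, 20)
    second: np.ndarray  # (P, 20, 20) in pair_indices order

    def copy(self) -> "GammaParams":
        return GammaParams(self.first.copy(), self.second.copy())


@dataclass
class InferenceConfig:
    """Hyperparameters of the moment-matching fit.

    Defaults follow the published framework settings: Adam with learning rate
    0.03 for 300 steps, l2 strengths 1e-3 (main) and 1e-4 (interactions),
    local-consistency multiplier 1e5, and mean-field inversion regularization
    50.  The early-stopping rule (relative loss change below ``early_stop_tol``
    over a ``early_stop_window``-step window) and the initialization
    pseudocount are this implementation's choices.
    """

    lambda_main: float = 1e-3
    lambda_int: float = 1e-4
    rho: float = 1e5
    lambda_reg: float = 50.0
    learning_rate: float = 0.03
    max_steps: int = 300
    early_stop_tol: float = 1e-6
    early_stop_window: int = 10
    pseudocount: float = 1e-6
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        for name in (
            "lambda_main", "lambda_int", "rho", "lambda_reg",
            "learning_rate", "early_stop_tol", "pseudocount",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def gamma_to_marginals(
    gamma: GammaParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Amino-acid marginals (nu1, nu2) and codon marginals (mu1, mu2).

    Codons encoding the same amino acid receive equal mass, so the
    amino-acid-level constraint set is enforced by construction.
    """
    ac, mult = ALPHABET.ac_map, ALPHABET.multiplicity.astype(float)
    nu1 = _softmax(gamma.first.reshape(gamma.first.shape[0], -1)).reshape(
        gamma.first.shape
    )
    P = gamma.second.shape[0]
    nu2 = _softmax(gamma.second.reshape(P, -1)).reshape(P, 20, 20)
    s1 = nu1 @ mult
    mu1 = nu1[:, ac] / s1[:, None]
    s2 = np.einsum("a,pab,b->p", mult, nu2, mult)
    mu2 = nu2[:, ac][:, :, ac] / s2[:, None, None]
    return nu1, nu2, mu1, mu2


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


class _TrajectoryObjective:
    """Loss + gradient engine for the moment-matching objective.

    Pre-allocates the per-round propagation buffers and implements the
    forward recursion and its reverse-mode adjoint with batched 61x61 matrix
    products (one shared mutation kernel across positions).
    """

    def __init__(
        self,
        data: dict[int, EmpiricalFrequencies],
        model: MutationModel,
        wildtype: CodonSequence,
        config: InferenceConfig,
    ) -> None:
        if not data:
            raise ValueError("no sequenced rounds supplied")
        if model.overrides:
            raise NotImplementedError(
                "inference assumes one shared mutation kernel across positions"
            )
        self.config = config
        self.g = model.kernel
        self.wt = wildtype
        self.L = wildtype.length
        self.iu, self.ju = pair_indices(self.L)
        self.P = self.iu.size
        self.rounds = sorted(data)
        self.Rmax = max(self.rounds)
        self.f1 = {r: data[r].first for r in self.rounds}
        self.f2 = {r: data[r].second for r in self.rounds}
        for r in self.rounds:
            if self.f1[r].shape != (self.L, 61):
                raise ValueError(f"round {r} frequencies inconsistent with wild type")
        self.ac = ALPHABET.ac_map
        self.mult = ALPHABET.multiplicity.astype(float)
        self.Tmat = np.zeros((61, 20))
        self.Tmat[np.arange(61), self.ac] = 1.0
        R, L, P = self.Rmax, self.L, self.P
        self.M1 = np.zeros((R + 1, L, 61))
        self.W1 = np.zeros((R, L, 61))
        self.S1 = np.zeros((R, L, 61))
        self.M2 = np.zeros((R + 1, P, 61, 61))
        self.W2 = np.zeros((R, P, 61, 61))
        self.S2 = np.zeros((R, P, 61, 61))
        self.M1[0, np.arange(L), wildtype.codons] = 1.0
        self.M2[0, np.arange(P), wildtype.codons[self.iu], wildtype.codons[self.ju]] = 1.0

    # ---------------------------------------------------------------- loss
    def loss_and_grad(
        self, gamma: GammaParams, want_grad: bool = True
    ) -> tuple[float, GammaParams | None]:
        cfg = self.config
        g, gT = self.g, self.g.T
        nu1, nu2, mu1, mu2 = gamma_to_marginals(gamma)
        s1 = nu1 @ self.mult
        s2 = np.einsum("a,pab,b->p", self.mult, nu2, self.mult)
        v1, V2 = mu1, mu2

        # forward propagation (denominators are round-independent)
        D1 = v1 @ gT
        D2 = np.matmul(g, np.matmul(V2, gT))
        for r in range(self.Rmax):
            np.divide(self.M1[r], D1, out=self.W1[r])
            np.matmul(self.W1[r], g, out=self.S1[r])
            np.multiply(v1, self.S1[r], out=self.M1[r + 1])
            np.divide(self.M2[r], D2, out=self.W2[r])
            np.matmul(gT, np.matmul(self.W2[r], g), out=self.S2[r])
            np.multiply(V2, self.S2[r], out=self.M2[r + 1])

        loss = 0.0
        for r in self.rounds:
            loss -= _masked_xlogy(self.f1[r], self.M1[r])
            loss -= 2.0 * _masked_xlogy(self.f2[r], self.M2[r])

        # local-consistency penalty on the amino-acid marginals
        rowm = nu2.sum(axis=2)  # (P, 20): partner-marginal for the smaller position
        colm = nu2.sum(axis=1)  # (P, 20): for the larger position
        marg = np.zeros_like(nu1)
        np.add.at(marg, self.iu, rowm)
        np.add.at(marg, self.ju, colm)
        delta = nu1 - marg / (self.L - 1)
        penalty = float((delta**2).sum())
        loss += cfg.rho * penalty

        reg = cfg.lambda_main * float((gamma.first**2).sum()) + 2.0 * cfg.lambda_int * float(
            (gamma.second**2).sum()
        )
        loss += reg

        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss (|gamma1|={np.abs(gamma.first).max():.3g}, "
                f"|gamma2|={np.abs(gamma.second).max():.3g})"
            )
        if not want_grad:
            return loss, None

        # ------------------------------------------------------- backward
        v1_bar = np.zeros_like(v1)
        D1_bar = np.zeros_like(D1)
        M1_bar = np.zeros_like(self.M1[0])
        V2_bar = np.zeros_like(V2)
        D2_bar = np.zeros_like(D2)
        M2_bar = np.zeros_like(self.M2[0])
        for r in range(self.Rmax, 0, -1):
            if r in self.f1:
                M1_bar -= _safe_ratio(self.f1[r], self.M1[r])
                M2_bar -= 2.0 * _safe_ratio(self.f2[r], self.M2[r])
            # first order: M_r = v1 * (W @ g) with W = M_{r-1} / D1
            v1_bar += M1_bar * self.S1[r - 1]
            S_bar = M1_bar * v1
            W_bar = (S_bar @ gT) / D1  # adjoint of W, pre-divided by D1
            D1_bar -= W_bar * self.W1[r - 1]
            M1_bar = W_bar
            # second order, same shape with the product kernel
            V2_bar += M2_bar * self.S2[r - 1]
            S2_bar = M2_bar * V2
            W2_bar = np.matmul(g, np.matmul(S2_bar, gT)) / D2
            D2_bar -= W2_bar * self.W2[r - 1]
            M2_bar = W2_bar
        v1_bar += D1_bar @ g
        V2_bar += np.matmul(gT, np.matmul(D2_bar, g))

        # mu -> nu (shared synonymous mass with normalization by s)
        nu1_bar = (v1_bar @ self.Tmat - self.mult[None, :] * (v1_bar * v1).sum(axis=1)[:, None]) / s1[:, None]
        inner = (V2_bar * V2).sum(axis=(1, 2))
        agg = np.matmul(np.matmul(self.Tmat.T, V2_bar), self.Tmat)  # (P, 20, 20)
        nu2_bar = (
            agg - np.outer(self.mult, self.mult)[None] * inner[:, None, None]
        ) / s2[:, None, None]

        # penalty adjoints (direct in nu space)
        nu1_bar += cfg.rho * 2.0 * delta
        scale = -cfg.rho * 2.0 / (self.L - 1)
        nu2_bar += scale * (delta[self.iu][:, :, None] + delta[self.ju][:, None, :])

        # softmax adjoints
        g1_bar = nu1 * (nu1_bar - (nu1 * nu1_bar).sum(axis=1, keepdims=True))
        flat = nu2.reshape(self.P, -1)
        flat_bar = nu2_bar.reshape(self.P, -1)
        g2_bar = (flat * (flat_bar - (flat * flat_bar).sum(axis=1, keepdims=True))).reshape(
            self.P, 20, 20
        )

        g1_bar += 2.0 * cfg.lambda_main * gamma.first
        g2_bar += 4.0 * cfg.lambda_int * gamma.second
        return loss, GammaParams(g1_bar, g2_bar)

    def predicted_marginals(self, gamma: GammaParams) -> dict[int, np.ndarray]:
        """First-order propagated marginals mu^(r) at the sequenced rounds."""
        self.loss_and_grad(gamma, want_grad=False)
        return {r: self.M1[r].copy() for r in self.rounds}


def _masked_xlogy(f: np.ndarray, m: np.ndarray) -> float:
    mask = f > 0
    out = np.zeros_like(m)
    np.log(m, out=out, where=mask)
    return float((f * out).sum())


def _safe_ratio(f: np.ndarray, m: np.ndarray) -> np.ndarray:
    return np.divide(f, m, out=np.zeros_like(m), where=f > 0)


def trajectory_loss(
    gamma: GammaParams,
    data: dict[int, EmpiricalFrequencies],
    model: MutationModel,
    wildtype: CodonSequence,
    config: InferenceConfig | None = None,
) -> float:
    """Scalar moment-matching objective at ``gamma``."""
    obj = _TrajectoryObjective(data, model, wildtype, config or InferenceConfig())
    loss, _ = obj.loss_and_grad(gamma, want_grad=False)
    return loss


def trajectory_loss_grad(
    gamma: GammaParams,
    data: dict[int, EmpiricalFrequencies],
    model: MutationModel,
    wildtype: CodonSequence,
    config: InferenceConfig | None = None,
) -> tuple[float, GammaParams]:
    """Objective and its exact reverse-mode gradient at ``gamma``."""
    obj = _TrajectoryObjective(data, model, wildtype, config or InferenceConfig())
    loss, grad = obj.loss_and_grad(gamma)
    return loss, grad


def initialize_gamma(
    data: dict[int, EmpiricalFrequencies], pseudocount: float
) -> GammaParams:
    """Log amino-acid frequencies of the last sequenced round (plus pseudocount)."""
    last = data[max(data)]
    faa1, faa2 = aggregate_to_amino_acids(last)
    return GammaParams(np.log(faa1 + pseudocount), np.log(faa2 + pseudocount))


@dataclass
class FitResult:
    """Outcome of the moment-matching optimization."""

    gamma: GammaParams
    nu_first: np.ndarray  # (L, 20)
    nu_second: np.ndarray  # (P, 20, 20)
    mu_first: np.ndarray  # (L, 61)
    mu_second: np.ndarray  # (P, 61, 61)
    loss_trace: np.ndarray
    n_steps: int
    converged_early: bool
    config: InferenceConfig = field(repr=False, default=None)


def fit_mean_parameters(
    data: dict[int, EmpiricalFrequencies],
    model: MutationModel,
    wildtype: CodonSequence,
    config: InferenceConfig | None = None,
) -> FitResult:
    """Fit the mean parameters by deterministic Adam on the trajectory loss.

    Starts from the documented log-frequency initialization, runs at most
    ``config.max_steps`` Adam steps, stops early when the relative loss change
    over the early-stopping window falls below tolerance, and returns the
    parameters with the lowest loss seen (never worse than the
    initialization).  Identical inputs give bit-identical results.
    """
    cfg = config or InferenceConfig()
    if cfg.optimizer != "adam":
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    obj = _TrajectoryObjective(data, model, wildtype, cfg)
    gamma = initialize_gamma(data, cfg.pseudocount)

    theta = np.concatenate([gamma.first.ravel(), gamma.second.ravel()])
    n1 = gamma.first.size

    def unpack(vec: np.ndarray) -> GammaParams:
        return GammaParams(
            vec[:n1].reshape(gamma.first.shape),
            vec[n1:].reshape(gamma.second.shape),
        )

    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    trace = []
    best_loss, best_theta = np.inf, theta.copy()
    converged = False
    step = 0
    for step in range(1, cfg.max_steps + 1):
        try:
            loss, grad = obj.loss_and_grad(unpack(theta))
        except FloatingPointError as exc:
            raise FloatingPointError(f"diverged at step {step}: {exc}") from exc
        trace.append(loss)
        if loss < best_loss:
            best_loss, best_theta = loss, theta.copy()
        gvec = np.concatenate([grad.first.ravel(), grad.second.ravel()])
        m = beta1 * m + (1 - beta1) * gvec
        v = beta2 * v + (1 - beta2) * gvec**2
        mhat = m / (1 - beta1**step)
        vhat = v / (1 - beta2**step)
        theta = theta - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        w = cfg.early_stop_window
        if len(trace) > w:
            rel = abs(trace[-1 - w] - trace[-1]) / max(abs(trace[-1 - w]), 1e-12)
            if rel < cfg.early_stop_tol:
                converged = True
                break

    gamma_hat = unpack(best_theta)
    nu1, nu2, mu1, mu2 = gamma_to_marginals(gamma_hat)
    return FitResult(
        gamma=gamma_hat,
        nu_first=nu1,
        nu_second=nu2,
        mu_first=mu1,
        mu_second=mu2,
        loss_trace=np.array(trace),
        n_steps=step,
        converged_early=converged,
        config=cfg,
    )


def invert_to_canonical(
    nu_first: np.ndarray,
    nu_second: np.ndarray,
    lambda_reg: float = 50.0,
    reference: np.ndarray | None = None,
) -> PottsModel:
    """Mean-field inversion of the estimated marginals to canonical parameters.

    Builds the connected-correlation matrix C_ij(a, b) = nu_ij(a, b) -
    nu_i(a) nu_j(b) over the L x (q - 1) dimensions of a reference-state
    gauge (``reference`` amino acid dropped at each site; defaults to each
    site's most probable amino acid), regularizes the diagonal with
    ``lambda_reg``, and sets the couplings to minus the inverse.  Fields come
    from the mean-field self-consistency relation

        h_i(a) = log(nu_i(a) / nu_i(ref_i)) - sum_{j != i, b} e_ij(a, b) nu_j(b).
    """
    nu1 = np.asarray(nu_first, dtype=float)
    L = nu1.shape[0]
    iu, ju = pair_indices(L)
    if reference is None:
        reference = np.argmax(nu1, axis=1)
    ref = np.asarray(reference, dtype=np.intp)
    keep = [np.flatnonzero(np.arange(20) != ref[i]) for i in range(L)]
    q1 = 19
    C = np.zeros((L * q1, L * q1))
    for i in range(L):
        blk = np.diag(nu1[i]) - np.outer(nu1[i], nu1[i])
        C[i * q1 : (i + 1) * q1, i * q1 : (i + 1) * q1] = blk[np.ix_(keep[i], keep[i])]
    for p in range(iu.size):
        i, j = int(iu[p]), int(ju[p])
        blk = nu_second[p] - np.outer(nu1[i], nu1[j])
        sub = blk[np.ix_(keep[i], keep[j])]
        C[i * q1 : (i + 1) * q1, j * q1 : (j + 1) * q1] = sub
        C[j * q1 : (j + 1) * q1, i * q1 : (i + 1) * q1] = sub.T
    A = C + lambda_reg * np.eye(L * q1)
    advice = (
        f"(C + {lambda_reg} I) is numerically singular; increase lambda_reg "
        "to exceed the magnitude of the most negative eigenvalue of C"
    )
    try:
        J = -np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(advice) from exc
    residual = np.abs(A @ (-J) - np.eye(L * q1)).max()
    if not np.isfinite(J).all() or residual > 1e-6:
        raise np.linalg.LinAlgError(advice)
    e = np.zeros((iu.size, 20, 20))
    for p in range(iu.size):
        i, j = int(iu[p]), int(ju[p])
        e[p][np.ix_(keep[i], keep[j])] = J[
            i * q1 : (i + 1) * q1, j * q1 : (j + 1) * q1
        ]
    nu_safe = np.maximum(nu1, 1e-300)
    h = np.log(nu_safe) - np.log(nu_safe[np.arange(L), ref])[:, None]
    for p in range(iu.size):
        i, j = int(iu[p]), int(ju[p])
        h[i] -= e[p] @ nu1[j]
        h[j] -= e[p].T @ nu1[i]
    return PottsModel(h, e)


def infer_landscape(
    data: dict[int, EmpiricalFrequencies],
    model: MutationModel,
    wildtype: CodonSequence,
    config: InferenceConfig | None = None,
) -> tuple[PottsModel, FitResult]:
    """Full inference: fit mean parameters, then invert to a Potts model.

    The inversion's reference gauge is anchored at the wild-type amino acids,
    matching the mutation-effect convention.
    """
    cfg = config or InferenceConfig()
    fit = fit_mean_parameters(data, model, wildtype, cfg)
    landscape = invert_to_canonical(
        fit.nu_first, fit.nu_second, cfg.lambda_reg, reference=wildtype.aa_indices()
    )
    return landscape, fit
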