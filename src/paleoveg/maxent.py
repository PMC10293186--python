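"""Presence-background maximum-entropy niche models.

The model is the Gibbs distribution over background cells
``q(x) = exp(lambda . f(x)) / Z`` whose feature expectations match the
presence sample, subject to an L1 penalty.  Fitting maximizes the convex
penalized log-likelihood

    mean_presence(lambda . f(x)) - log Z - beta * sum_j s_j |lambda_j|

where ``Z = sum_background exp(lambda . f(x))`` and ``s_j`` is the
empirical presence standard deviation of feature j (floored to avoid
runaway weights on presence-constant features).  At the optimum the KKT
conditions bound the gap between presence and background feature means by
``beta * s_j`` for every feature.

Features follow the conventional presence-background classes: linear,
quadratic, pairwise product, and two-sided hinge with evenly spaced knots,
all mapped to [0, 1] using the training min/max per variable.  The
exponential output ("raw") is the relative occurrence rate normalized over
the training background; the bounded "cloglog" transform
``1 - exp(-e^H q)`` (H = entropy of the fitted background distribution)
gives a per-cell probability of occurrence suitable for compositing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .errors import ConvergenceError
from .grids import NINE_PREDICTORS, ClimateStack, GridGeometry, SuitabilitySurface
from .synthetic import OccurrenceSet

DEFAULT_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")
DEFAULT_N_HINGE_KNOTS = 31
DEFAULT_BETA = 1.0
DEFAULT_N_BACKGROUND = 10_000

#: Minimum penalty scale per feature (on the [0,1] feature range).
S_FLOOR = 1e-2

MODEL_FORMAT_VERSION = 1


@dataclass
class FeatureExpansion:
    """Feature definitions plus the training min/max used for scaling."""

    variables: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    classes: tuple[str, ...] = DEFAULT_FEATURE_CLASSES
    n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS

    def __post_init__(self):
        self.variables = tuple(self.variables)
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != (len(self.variables),) or self.maxs.shape != self.mins.shape:
            raise ValueError("mins/maxs must match the variable list")
        unknown = set(self.classes) - set(DEFAULT_FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if "hinge" in self.classes and self.n_hinge_knots < 1:
            raise ValueError("n_hinge_knots must be at least 1")

    @classmethod
    def from_samples(
        cls,
        env_frames: Sequence[pd.DataFrame],
        variables: Sequence[str],
        classes: Sequence[str] = DEFAULT_FEATURE_CLASSES,
        n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS,
    ) -> "FeatureExpansion":
        """Scaling ranges from the union of presence and background samples."""
        variables = tuple(variables)
        combined = pd.concat([f[list(variables)] for f in env_frames], axis=0)
        return cls(
            variables=variables,
            mins=combined.min(axis=0).to_numpy(dtype=float),
            maxs=combined.max(axis=0).to_numpy(dtype=float),
            classes=tuple(classes),
            n_hinge_knots=int(n_hinge_knots),
        )

    @property
    def knots(self) -> np.ndarray:
        k = self.n_hinge_knots
        return np.arange(1, k + 1) / (k + 1)

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        v = self.variables
        if "linear" in self.classes:
            names += [f"lin:{a}" for a in v]
        if "quadratic" in self.classes:
            names += [f"quad:{a}" for a in v]
        if "product" in self.classes:
            names += [f"prod:{a}*{b}" for a, b in combinations(v, 2)]
        if "hinge" in self.classes:
            for a in v:
                names += [f"hingef:{a}@{k:.6g}" for k in self.knots]
                names += [f"hinger:{a}@{k:.6g}" for k in self.knots]
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _scale(self, X: np.ndarray, clamp: bool) -> tuple[np.ndarray, np.ndarray]:
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        z = (X - self.mins) / span
        out_of_range = np.any((z < 0) | (z > 1), axis=1)
        if clamp:
            z = np.clip(z, 0.0, 1.0)
        return z, out_of_range

    def transform(
        self, env, clamp: bool = True, return_mask: bool = False
    ):
        """(n, m) design matrix; optionally also the out-of-range row mask.

        ``env`` is a DataFrame with the model variables as columns or an
        (n, k) array in variable order.  Values outside the training range
        are clamped to the range boundary when ``clamp`` is true.
        """
        if isinstance(env, pd.DataFrame):
            X = env[list(self.variables)].to_numpy(dtype=float)
        else:
            X = np.asarray(env, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.variables):
            raise ValueError("env must have one column per model variable")
        z, mask = self._scale(X, clamp)
        n, k = z.shape
        blocks: list[np.ndarray] = []
        if "linear" in self.classes:
            blocks.append(z)
        if "quadratic" in self.classes:
            blocks.append(z**2)
        if "product" in self.classes:
            pairs = list(combinations(range(k), 2))
            if pairs:
                ia = [a for a, _ in pairs]
                ib = [b for _, b in pairs]
                blocks.append(z[:, ia] * z[:, ib])
        if "hinge" in self.classes:
            kn = self.knots
            for i in range(k):
                col = z[:, i : i + 1]
                blocks.append(np.maximum(0.0, (col - kn) / (1.0 - kn)))
                blocks.append(np.maximum(0.0, (kn - col) / kn))
        F = np.concatenate(blocks, axis=1) if blocks else np.empty((n, 0))
        if return_mask:
            return F, mask
        return F

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "classes": list(self.classes),
            "n_hinge_knots": self.n_hinge_knots,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpansion":
        return cls(
            variables=tuple(d["variables"]),
            mins=np.asarray(d["mins"]),
            maxs=np.asarray(d["maxs"]),
            classes=tuple(d["classes"]),
            n_hinge_knots=int(d["n_hinge_knots"]),
        )


@dataclass
class BackgroundSample:
    """Uniformly sampled landscape cells with their climate values."""

    rows: np.ndarray
    cols: np.ndarray
    env: pd.DataFrame
    geometry: GridGeometry

    def __len__(self) -> int:
        return len(self.env)


@dataclass
class NicheModel:
    """Fitted feature weights and training metadata for one unit."""

    vu_id: str
    features: FeatureExpansion
    weights: np.ndarray
    log_z: float
    entropy: float
    beta: float
    penalty_scales: np.ndarray
    n_presence: int
    n_background: int
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def score(self, env, clamp: bool = True) -> np.ndarray:
        """Linear score lambda . f(x)."""
        return self.features.transform(env, clamp=clamp) @ self.weights

    def raw(self, env, clamp: bool = True) -> np.ndarray:
        """Relative occurrence rate, normalized over the training background."""
        return np.exp(self.score(env, clamp=clamp) - self.log_z)

    def cloglog(self, env, clamp: bool = True) -> np.ndarray:
        """Probability-of-occurrence transform 1 - exp(-e^H q), in [0, 1]."""
        return np.clip(1.0 - np.exp(-np.exp(self.entropy) * self.raw(env, clamp=clamp)), 0.0, 1.0)

    # -- serialization (versioned structured text) ---------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "vu_id": self.vu_id,
                "features": self.features.to_dict(),
                "weights": self.weights.tolist(),
                "log_z": self.log_z,
                "entropy": self.entropy,
                "beta": self.beta,
                "penalty_scales": self.penalty_scales.tolist(),
                "n_presence": self.n_presence,
                "n_background": self.n_background,
                "seed": self.seed,
            },
            indent=1,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "NicheModel":
        d = json.loads(Path(path).read_text())
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return cls(
            vu_id=d["vu_id"],
            features=FeatureExpansion.from_dict(d["features"]),
            weights=np.asarray(d["weights"], dtype=float),
            log_z=float(d["log_z"]),
            entropy=float(d["entropy"]),
            beta=float(d["beta"]),
            penalty_scales=np.asarray(d["penalty_scales"], dtype=float),
            n_presence=int(d["n_presence"]),
            n_background=int(d["n_background"]),
            seed=d.get("seed"),
        )


@dataclass
class EvaluationResult:
    vu_id: str
    auc: float
    n_test: int
    n_background: int

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def env_at_points(
    stack: ClimateStack, occ: OccurrenceSet, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Climate values of the cells containing each occurrence point."""
    variables = tuple(variables) if variables else stack.var_names
    row, col = stack.geometry.cell_of(occ.x, occ.y)
    return pd.DataFrame({v: stack.layer(v)[row, col] for v in variables})


def split_occurrences(
    occ: OccurrenceSet, test_fraction: float = 0.25, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random holdout split: exactly floor(test_fraction * n) test points."""
    n = len(occ)
    if n < 2:
        raise ValueError("at least two occurrences are required to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n_test = int(np.floor(test_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    te, tr = perm[:n_test], perm[n_test:]
    mk = lambda idx: OccurrenceSet(occ.vu_id, occ.x[idx], occ.y[idx], occ.provenance)
    return mk(tr), mk(te)


def sample_background(
    stack: ClimateStack,
    n_background: int = DEFAULT_N_BACKGROUND,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> BackgroundSample:
    """Uniform sample of valid cells without replacement.

    Cells carrying a missing value in any requested layer are excluded.
    If the grid holds fewer valid cells than requested, all of them are
    used (with a warning).
    """
    if n_background < 100:
        raise ValueError("n_background must be at least 100")
    variables = tuple(variables) if variables else stack.var_names
    finite = np.ones(stack.geometry.shape, dtype=bool)
    for v in variables:
        finite &= np.isfinite(stack.layer(v))
    rows, cols = np.nonzero(finite)
    if rows.size == 0:
        raise ValueError("no valid cells to sample background from")
    if rows.size <= n_background:
        if rows.size < n_background:
            warnings.warn(
                f"only {rows.size} valid cells available; using all of them",
                UserWarning,
                stacklevel=2,
            )
        pick = np.arange(rows.size)
    else:
        pick = np.random.default_rng(seed).choice(rows.size, n_background, replace=False)
    r, c = rows[pick], cols[pick]
    env = pd.DataFrame({v: stack.layer(v)[r, c] for v in variables})
    return BackgroundSample(rows=r, cols=c, env=env, geometry=stack.geometry)


def _objective(theta, Xp_mean, Xb, s, beta):
    m = Xp_mean.size
    lam = theta[:m] - theta[m:]
    sb = Xb @ lam
    log_z = logsumexp(sb)
    q = np.exp(sb - log_z)
    f = -Xp_mean @ lam + log_z + beta * (s @ (theta[:m] + theta[m:]))
    g = -Xp_mean + Xb.T @ q
    grad = np.concatenate([g + beta * s, -g + beta * s])
    return f, grad


def fit_maxent(
    train: OccurrenceSet,
    background: BackgroundSample,
    stack: ClimateStack,
    features: FeatureExpansion | None = None,
    beta: float = DEFAULT_BETA,
    variables: Sequence[str] | None = None,
    feature_classes: Sequence[str] = DEFAULT_FEATURE_CLASSES,
    n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS,
    max_iter: int = 5000,
    grad_tol: float = 1e-6,
    seed: int | None = None,
) -> NicheModel:
    """Fit the penalized maximum-entropy model for one unit.

    The convex objective is solved by L-BFGS-B on the positive/negative
    weight split (an exact reformulation of the L1 penalty) to the stated
    projected-gradient tolerance.  The fitted model stores log Z and the
    entropy H of the background distribution, the per-feature KKT
    residuals, and the solver's objective trace.
    """
    if len(train) < 10:
        raise ValueError("at least 10 training presences are required")
    if len(background) < 10:
        raise ValueError("at least 10 background cells are required")
    if len(background) < 100:
        warnings.warn(
            "fewer than 100 background cells; estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    if beta < 0:
        raise ValueError("beta must be non-negative")

    if variables is None:
        variables = (
            tuple(background.env.columns)
            if features is None
            else features.variables
        )
    presence_env = env_at_points(stack, train, variables)
    if features is None:
        features = FeatureExpansion.from_samples(
            [presence_env, background.env],
            variables,
            classes=tuple(feature_classes),
            n_hinge_knots=n_hinge_knots,
        )
    Xp = features.transform(presence_env)
    Xb = features.transform(background.env)
    m = features.n_features
    Xp_mean = Xp.mean(axis=0)
    s = np.maximum(Xp.std(axis=0), S_FLOOR)

    history: list[float] = []

    def cb(theta):
        history.append(_objective(theta, Xp_mean, Xb, s, beta)[0])

    res = minimize(
        _objective,
        x0=np.zeros(2 * m),
        args=(Xp_mean, Xb, s, beta),
        method="L-BFGS-B",
        jac=True,
        bounds=[(0.0, None)] * (2 * m),
        callback=cb,
        options={"maxiter": max_iter, "maxfun": 4 * max_iter, "gtol": grad_tol, "ftol": 1e-14},
    )
    if res.status == 2:
        raise ConvergenceError(
            f"solver failed for unit {train.vu_id!r}: {res.message}",
            details={"status": res.status, "nit": res.nit, "message": str(res.message)},
        )
    lam = res.x[:m] - res.x[m:]
    sb = Xb @ lam
    log_z = float(logsumexp(sb))
    q = np.exp(sb - log_z)
    nz = q > 0
    entropy = float(-(q[nz] * np.log(q[nz])).sum())
    kkt = np.abs(Xp_mean - Xb.T @ q)
    if res.status == 1 and np.any(kkt > beta * s + 1e-4):
        raise ConvergenceError(
            f"iteration cap reached before KKT tolerance for unit {train.vu_id!r}",
            details={"nit": res.nit, "max_kkt_excess": float((kkt - beta * s).max())},
        )
    return NicheModel(
        vu_id=train.vu_id,
        features=features,
        weights=lam,
        log_z=log_z,
        entropy=entropy,
        beta=beta,
        penalty_scales=s,
        n_presence=len(train),
        n_background=len(background),
        seed=seed,
        diagnostics={
            "objective_history": history,
            "n_iterations": int(res.nit),
            "converged": bool(res.status == 0),
            "kkt_residuals": kkt,
            "final_objective": float(res.fun),
        },
    )


def predict_suitability(
    model: NicheModel,
    stack: ClimateStack,
    output_form: str = "cloglog",
    clamp: bool = True,
) -> SuitabilitySurface:
    """Per-cell suitability of one stack under a fitted model.

    ``raw`` is the relative occurrence rate normalized over the training
    background (sums to 1 over those cells); ``cloglog`` is the bounded
    probability-of-occurrence transform.  Cells whose predictors fall
    outside the training range are clamped to the range boundary and
    flagged in the clamping mask.
    """
    if output_form not in ("raw", "cloglog"):
        raise ValueError("output_form must be 'raw' or 'cloglog'")
    env = pd.DataFrame(
        {v: stack.layer(v).ravel() for v in model.features.variables}
    )
    F, mask = model.features.transform(env, clamp=clamp, return_mask=True)
    score = F @ model.weights
    raw = np.exp(score - model.log_z)
    if output_form == "raw":
        # raw is a normalized rate, not a probability: store clipped to [0,1]
        vals = np.clip(raw, 0.0, 1.0)
    else:
        vals = np.clip(1.0 - np.exp(-np.exp(model.entropy) * raw), 0.0, 1.0)
    shape = stack.geometry.shape
    return SuitabilitySurface(
        vu_id=model.vu_id,
        age_ka=stack.age_ka,
        geometry=stack.geometry,
        values=vals.reshape(shape),
        corrected=False,
        clamp_mask=mask.reshape(shape) if clamp else None,
    )


def auc_presence_background(
    presence_scores: np.ndarray, background_scores: np.ndarray
) -> float:
    """Exact rank AUC: P(presence > background) + 0.5 P(tie)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([b, p]))
    rp = ranks[b.size :].sum()
    return float((rp - p.size * (p.size + 1) / 2) / (p.size * b.size))


def evaluate_auc(
    model: NicheModel,
    test: OccurrenceSet,
    background: BackgroundSample,
    stack: ClimateStack,
) -> EvaluationResult:
    """Holdout AUC of test presences against the background sample."""
    if len(test) < 1:
        raise ValueError("at least one test point is required")
    test_env = env_at_points(stack, test, model.features.variables)
    ps = model.score(test_env)
    bs = model.score(background.env[list(model.features.variables)])
    return EvaluationResult(
        vu_id=model.vu_id,
        auc=auc_presence_background(ps, bs),
        n_test=len(test),
        n_background=len(background),
    )
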