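"""Second-order Maximum Noise Entropy (MNE) encoding model.

The model assigns each reduced stimulus patch ``s`` an event probability

    P(event | s) = 1 / (1 + exp(a + s.h + s' J s))

with scalar bias ``a``, linear kernel ``h`` and symmetric quadratic kernel
``J``.  It is the maximum-entropy model constrained to match the observed
mean event rate, event-triggered average (STA) and event-triggered
covariance (STC): minimizing the average cross-entropy between the
trial-averaged response and the model probability enforces exactly those
moment conditions at a stationary point.

The public surface follows the statsmodels idiom: build a
:class:`MaximumNoiseEntropyModel` from data, call :meth:`fit` to obtain an
:class:`MNEResults`, then evaluate on held-out data against a shuffle null
and extract receptive-field features from the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .events import AlignedDataset
from .spectro import PcaReduction

__all__ = [
    "MaximumNoiseEntropyModel",
    "MNEResults",
    "ModelEvaluation",
    "RfFeature",
    "predict",
    "nll_and_gradient",
    "pack_params",
    "unpack_params",
]


# ---------------------------------------------------------------------------
# parameter packing: theta = [a, h (K), upper triangle of J (K(K+1)/2)]

def pack_params(a: float, h: np.ndarray, J: np.ndarray) -> np.ndarray:
    K = len(h)
    iu = np.triu_indices(K)
    return np.concatenate(([a], h, np.asarray(J)[iu]))


def unpack_params(theta: np.ndarray, K: int) -> tuple[float, np.ndarray, np.ndarray]:
    a = float(theta[0])
    h = np.asarray(theta[1 : 1 + K])
    J = np.zeros((K, K))
    iu = np.triu_indices(K)
    J[iu] = theta[1 + K :]
    J = J + J.T - np.diag(np.diag(J))
    return a, h, J


def _logistic_argument(a: float, h: np.ndarray, J: np.ndarray,
                       X: np.ndarray) -> np.ndarray:
    return a + X @ h + np.einsum("ij,ij->i", X @ J, X)


def predict(model, X: np.ndarray) -> np.ndarray:
    """Event probability per row of ``X`` under the logistic model.

    ``model`` is anything with attributes ``a``, ``h``, ``J`` (an
    :class:`MNEResults` or a ground-truth model).  Computed overflow-safely
    through the logistic sigmoid.
    """
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    z = _logistic_argument(model.a, model.h, model.J, X)
    return expit(-z)


def nll_and_gradient(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                     ridge: float = 0.0) -> tuple[float, np.ndarray]:
    """Average cross-entropy of the MNE model and its exact gradient.

    Targets ``y`` may be fractional (trial-averaged responses in [0, 1]);
    the loss is then the mean per-trial Bernoulli negative log-likelihood.
    An optional ridge penalty ``0.5 * ridge * (|h|^2 + |J|_F^2)`` is added
    for stability when the sample count is below the parameter count.
    Gradient is with respect to the packed ``[a, h, triu(J)]`` vector.
    """
    n, K = X.shape
    a, h, J = unpack_params(theta, K)
    z = _logistic_argument(a, h, J, X)
    # L_i = log(1 + e^z) - (1 - y) z, numerically via logaddexp
    nll = float(np.mean(np.logaddexp(0.0, z) - (1.0 - y) * z))
    p = expit(-z)
    r = (y - p) / n  # dL/dz_i
    ga = r.sum()
    gh = X.T @ r
    GJ = X.T @ (r[:, None] * X)  # symmetric K x K
    if ridge:
        nll += 0.5 * ridge * (h @ h + float(np.sum(J * J)))
        gh = gh + ridge * h
        GJ = GJ + ridge * J
    Gp = 2.0 * GJ
    np.fill_diagonal(Gp, np.diag(GJ))
    iu = np.triu_indices(K)
    return nll, np.concatenate(([ga], gh, Gp[iu]))


# ---------------------------------------------------------------------------


@dataclass
class ModelEvaluation:
    """Held-out performance of a fitted model against its shuffle null.

    ``p_value`` is the literal proportion of null similarities at or above
    the observed one; ``p_value_plus_one`` applies the (r+1)/(n+1)
    permutation convention.  ``significant`` uses the literal proportion at
    the configured alpha.
    """

    cosine_similarity: float
    null_similarities: np.ndarray
    p_value: float
    p_value_plus_one: float
    significant: bool
    alpha: float = 0.05
    null_params: list[tuple[float, np.ndarray, np.ndarray]] = field(
        default_factory=list, repr=False
    )


@dataclass
class RfFeature:
    """A spectrotemporal receptive-field feature.

    ``map`` is the feature back-projected to the time-frequency plane
    (time bins x frequency bins).  Quadratic features are unit-norm
    eigenvectors of J; ``eigenvalue > 0`` means the feature increases the
    exponent argument and therefore *decreases* event probability
    (inhibitory), ``eigenvalue < 0`` is excitatory.  The linear feature is
    ``h`` itself, stored in the orientation that increases the exponent.
    """

    map: np.ndarray
    kind: str  # "linear" | "quadratic"
    eigenvalue: float | None
    sign_class: str  # "inhibitory" | "excitatory"
    significant: bool
    reduced_vector: np.ndarray | None = None


def _cosine(u: np.ndarray, v: np.ndarray, centered: bool = False) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if centered:
        u = u - u.mean()
        v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise FloatingPointError("cosine similarity undefined for zero-norm vector")
    return float(u @ v / (nu * nv))


class MaximumNoiseEntropyModel:
    """Second-order MNE encoding model bound to an aligned dataset.

    Parameters
    ----------
    X : ndarray, shape (N, K)
        Reduced stimulus patches (one row per time bin).
    y : ndarray, shape (N,)
        Trial-averaged responses in [0, 1].
    train_mask, test_mask : boolean arrays, optional
        Held-out split; defaults to all rows training, no test rows.
    folds : list of index arrays, optional
        Cross-validation folds over the training rows, used for early
        stopping.  Without folds the model is fit to convergence on the
        full training block.
    ridge : float
        L2 penalty on h and J (default 1e-4) for stability when the row
        count is below the parameter count.

    Notes
    -----
    Optimization runs in per-dimension z-scored stimulus coordinates
    (statistics taken over the training rows) for conditioning; the
    fitted parameters are mapped back exactly to the original reduced
    coordinates, so predictions and reported (a, h, J) are unaffected by
    the internal standardization.
    """

    def __init__(self, X, y, train_mask=None, test_mask=None, folds=None,
                 ridge: float = 1e-4):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (N, K) and y length N")
        if y.min() < 0.0 or y.max() > 1.0:
            raise ValueError("y must lie in [0, 1]")
        self.X, self.y = X, y
        n = X.shape[0]
        self.train_mask = (
            np.ones(n, bool) if train_mask is None else np.asarray(train_mask, bool)
        )
        self.test_mask = (
            np.zeros(n, bool) if test_mask is None else np.asarray(test_mask, bool)
        )
        self.folds = folds
        self.ridge = float(ridge)
        mu = X[self.train_mask].mean(axis=0)
        sd = X[self.train_mask].std(axis=0)
        sd[sd < 1e-300] = 1.0
        self._mu, self._sd = mu, sd
        self._Xs = (X - mu) / sd

    @classmethod
    def from_aligned(cls, data: AlignedDataset, ridge: float = 1e-4
                     ) -> "MaximumNoiseEntropyModel":
        return cls(data.X, data.y, train_mask=data.train_mask,
                   test_mask=data.test_mask, folds=data.folds, ridge=ridge)

    @property
    def n_components(self) -> int:
        return self.X.shape[1]

    # -- fitting ------------------------------------------------------------

    def _initial_params(self, y_train: np.ndarray) -> np.ndarray:
        K = self.n_components
        ybar = float(np.clip(y_train.mean(), 1e-4, 1 - 1e-4))
        a0 = np.log(1.0 / ybar - 1.0)
        return pack_params(a0, np.zeros(K), np.zeros((K, K)))

    def _unstandardize(self, theta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Map (a, h, J) fitted on z-scored coordinates back to the
        original reduced coordinates (an exact reparameterization)."""
        a_s, h_s, J_s = unpack_params(theta, self.n_components)
        D = 1.0 / self._sd
        J = (J_s * D).T * D  # D J_s D
        Dh = D * h_s
        h = Dh - 2.0 * (J @ self._mu)
        a = a_s - Dh @ self._mu + self._mu @ J @ self._mu
        return float(a), h, J

    def _fit_block(self, train_idx, val_idx, y_train_full, maxiter, gtol,
                   ftol=2.22e-9, early_stopping=False):
        """One optimizer run; returns (params, validation NLL).

        With ``early_stopping`` the parameters at the best validation NLL
        along the optimization path are returned instead of the converged
        ones."""
        Xtr, ytr = self._Xs[train_idx], y_train_full[train_idx]
        theta0 = self._initial_params(ytr)
        state = {"best": np.inf, "theta": theta0.copy()}
        have_val = val_idx is not None and len(val_idx)
        if have_val:
            Xv, yv = self._Xs[val_idx], y_train_full[val_idx]
        if early_stopping and have_val:
            def callback(theta):
                v, _ = nll_and_gradient(theta, Xv, yv, 0.0)
                if v < state["best"]:
                    state["best"] = v
                    state["theta"] = theta.copy()
        else:
            callback = None
        res = minimize(
            nll_and_gradient, theta0, args=(Xtr, ytr, self.ridge),
            jac=True, method="L-BFGS-B", callback=callback,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("MNE fit diverged: non-finite loss")
        if not have_val:
            return res.x, float(res.fun)
        final_v, _ = nll_and_gradient(res.x, Xv, yv, 0.0)
        if callback is not None and state["best"] < final_v:
            return state["theta"], float(state["best"])
        return res.x, float(final_v)

    def fit(self, maxiter: int = 500, gtol: float = 1e-8,
            ftol: float = 2.22e-9, early_stopping: bool = False,
            y_train_override: np.ndarray | None = None) -> "MNEResults":
        """Fit by L-BFGS under three-fold cross-validation.

        With folds, each fold is held out once as a validation set (its
        NLL is recorded as the fold score) and the final parameters are
        the average of the fold models, a deterministic ensemble; without
        folds a single run on the full training block is performed.  By
        default each run proceeds to convergence under the ridge penalty,
        which keeps real and shuffled fits at comparable capacity — the
        property the eigenvalue significance test relies on;
        ``early_stopping=True`` instead returns each fold's parameters at
        its best validation NLL.

        ``y_train_override`` substitutes the training responses (used
        internally for the shuffle null; the test pairing is untouched).
        """
        y_full = self.y.copy()
        if y_train_override is not None:
            y_full = y_full.astype(float)
            y_full[self.train_mask] = y_train_override
        train_idx = np.flatnonzero(self.train_mask)
        if self.folds:
            thetas, scores = [], []
            for f in self.folds:
                tr = np.setdiff1d(train_idx, f)
                theta, score = self._fit_block(tr, f, y_full, maxiter, gtol,
                                               ftol, early_stopping)
                thetas.append(theta)
                scores.append(score)
            theta = np.mean(thetas, axis=0)
            fold_scores = scores
        else:
            theta, score = self._fit_block(train_idx, None, y_full, maxiter,
                                           gtol, ftol, early_stopping)
            fold_scores = [score]
        a, h, J = self._unstandardize(theta)
        return MNEResults(model=self, a=a, h=h, J=J,
                          fold_scores=np.asarray(fold_scores),
                          fit_meta={"maxiter": maxiter, "gtol": gtol,
                                    "ftol": ftol, "ridge": self.ridge,
                                    "early_stopping": early_stopping,
                                    "n_folds": len(self.folds or [])})


class MNEResults:
    """Fitted MNE model: parameters, held-out evaluation, RF features."""

    def __init__(self, model: MaximumNoiseEntropyModel, a: float,
                 h: np.ndarray, J: np.ndarray, fold_scores: np.ndarray,
                 fit_meta: dict):
        if not np.allclose(J, J.T, atol=1e-8):
            raise ValueError("J must be symmetric")
        if not (np.isfinite(a) and np.isfinite(h).all() and np.isfinite(J).all()):
            raise ValueError("non-finite fitted parameters")
        self.model = model
        self.a, self.h, self.J = float(a), h, 0.5 * (J + J.T)
        self.fold_scores = fold_scores
        self.fit_meta = fit_meta
        self.evaluation: ModelEvaluation | None = None

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        """Event probabilities; defaults to the bound design matrix."""
        return predict(self, self.model.X if X is None else X)

    # -- held-out evaluation and shuffle null -------------------------------

    def evaluate(self, n_shuffles: int = 200, seed: int | None = None,
                 alpha: float = 0.05, centered: bool = False,
                 progress: bool = False) -> ModelEvaluation:
        """Cosine similarity on the held-out block against a shuffle null.

        The null permutes the *training* responses over training rows (the
        test pairing is untouched), refits with identical optimizer
        settings, and predicts the unshuffled test stimuli.  ``p_value``
        is the proportion of null similarities >= the observed one;
        models are significant when that proportion is below ``alpha``.
        """
        m = self.model
        if not m.test_mask.any():
            raise ValueError("test set is empty")
        Xte, yte = m.X[m.test_mask], m.y[m.test_mask]
        obs = _cosine(self.predict(Xte), yte, centered=centered)
        rng = np.random.default_rng(seed)
        y_train = m.y[m.train_mask]
        nulls, null_params = [], []
        iterator = range(n_shuffles)
        if progress:
            from tqdm import tqdm  # local import: optional nicety
            iterator = tqdm(iterator, desc="shuffle null")
        for _ in iterator:
            y_shuf = rng.permutation(y_train)
            res = m.fit(maxiter=self.fit_meta["maxiter"],
                        gtol=self.fit_meta["gtol"],
                        ftol=self.fit_meta.get("ftol", 2.22e-9),
                        early_stopping=self.fit_meta.get("early_stopping",
                                                         False),
                        y_train_override=y_shuf)
            try:
                nulls.append(_cosine(res.predict(Xte), yte, centered=centered))
            except FloatingPointError:
                nulls.append(-np.inf)
            null_params.append((res.a, res.h, res.J))
        nulls = np.asarray(nulls)
        if n_shuffles:
            r = int(np.sum(nulls >= obs))
            p_lit = r / n_shuffles
            p_p1 = (r + 1) / (n_shuffles + 1)
            sig = p_lit < alpha
        else:
            p_lit = p_p1 = np.nan
            sig = False
        self.evaluation = ModelEvaluation(
            cosine_similarity=obs, null_similarities=nulls, p_value=p_lit,
            p_value_plus_one=p_p1, significant=bool(sig), alpha=alpha,
            null_params=null_params,
        )
        return self.evaluation

    # -- receptive-field features -------------------------------------------

    def quadratic_eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors of J, signs fixed so the
        largest-magnitude element of each eigenvector is positive."""
        w, V = np.linalg.eigh(self.J)
        flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
        flip[flip == 0] = 1.0
        return w, V * flip

    def extract_features(self, pca: PcaReduction,
                         null_params: list | None = None,
                         band: tuple[float, float] = (2.5, 97.5),
                         include_linear: bool = True) -> list[RfFeature]:
        """Back-project h and the eigenvectors of J to time-frequency maps.

        Significance of each quadratic candidate is judged against an
        extreme-eigenvalue null built from the shuffled fits: an
        eigenvalue is significant if it exceeds the upper ``band``
        percentile of the null distribution of *largest* eigenvalues, or
        falls below the lower percentile of the null *smallest*
        eigenvalues.  Controlling the extremes makes the test familywise
        across the K candidates, so a stimulus-independent unit yields
        approximately zero significant features in expectation.  The
        linear feature is significant if |h| exceeds the upper band edge
        of the null |h| distribution.  Without null fits all candidates
        are returned with ``significant=False``.
        """
        if null_params is None:
            null_params = (self.evaluation.null_params
                           if self.evaluation is not None else [])
        w, V = self.quadratic_eigensystem()
        K = len(w)
        lo_band = hi_band = None
        if null_params:
            null_eigs = [np.linalg.eigvalsh(Jn) for _, _, Jn in null_params]
            lo_band = np.percentile([e[0] for e in null_eigs], band[0])
            hi_band = np.percentile([e[-1] for e in null_eigs], band[1])
        feats: list[RfFeature] = []
        if include_linear and np.linalg.norm(self.h) > 0:
            h_sig = False
            if null_params:
                null_hnorm = [np.linalg.norm(hn) for _, hn, _ in null_params]
                h_sig = bool(
                    np.linalg.norm(self.h) > np.percentile(null_hnorm, band[1])
                )
            feats.append(RfFeature(
                map=self._to_map(pca, self.h / np.linalg.norm(self.h)),
                kind="linear", eigenvalue=None, sign_class="inhibitory",
                significant=h_sig, reduced_vector=self.h.copy(),
            ))
        for k in range(K):
            sig = False
            if lo_band is not None:
                sig = bool(w[k] < lo_band or w[k] > hi_band)
            feats.append(RfFeature(
                map=self._to_map(pca, V[:, k]),
                kind="quadratic", eigenvalue=float(w[k]),
                sign_class="inhibitory" if w[k] > 0 else "excitatory",
                significant=sig, reduced_vector=V[:, k].copy(),
            ))
        return feats

    @staticmethod
    def _to_map(pca: PcaReduction, v: np.ndarray) -> np.ndarray:
        full = pca.lift_direction(v)
        n_freq = int(round(np.sqrt(full.size)))
        if n_freq * n_freq != full.size:
            # non-square patch: caller reshapes; return flat
            return full
        return full.reshape(n_freq, n_freq)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary in the statsmodels spirit.

        Parameter magnitudes are reported on the scale of the exponent
        argument (the standard deviation of each term over the training
        stimuli, and eigenvalues of J in unit-variance stimulus
        coordinates) so they are comparable across stimuli regardless of
        the raw power units.
        """
        m = self.model
        Xtr = m.X[m.train_mask]
        lin = Xtr @ self.h
        quad = np.einsum("ij,ij->i", Xtr @ self.J, Xtr)
        J_std = (self.J * m._sd).T * m._sd
        w_std = np.linalg.eigvalsh(J_std)
        lines = [
            "Maximum Noise Entropy model (second order)",
            "=" * 46,
            f"observations (train/test): {int(m.train_mask.sum())}/"
            f"{int(m.test_mask.sum())}",
            f"stimulus dimensions (K):   {self.model.n_components}",
            f"ridge penalty:             {m.ridge:g}",
            f"bias a:                    {self.a:.4f}",
            f"linear term s.d.:          {lin.std():.4f}",
            f"quadratic term s.d.:       {quad.std():.4f}",
            "eigenvalues of J (unit-variance coords): "
            f"min {w_std[0]:.4f}, max {w_std[-1]:.4f}",
            f"fold validation NLL:       "
            + ", ".join(f"{s:.4f}" for s in self.fold_scores),
        ]
        if self.evaluation is not None:
            e = self.evaluation
            lines += [
                f"test cosine similarity:    {e.cosine_similarity:.4f}",
                f"shuffle p (literal/+1):    {e.p_value:.4f} / "
                f"{e.p_value_plus_one:.4f}  "
                f"({'significant' if e.significant else 'n.s.'} at "
                f"alpha={e.alpha})",
            ]
        return "\n".join(lines)
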