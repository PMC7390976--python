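"""Multivariate adaptive regression splines (additive hinge basis).

A from-scratch MARS regressor: greedy forward growth of mirrored hinge
pairs max(x - k, 0) / max(k - x, 0) followed by backward pruning under
generalised cross-validation (GCV),

    GCV(M) = RSS / n / (1 - C(M)/n)^2,   C(M) = M + penalty * (M - 1) / 2,

with the customary smoothing penalty of 3 per knot.  Basis functions are
additive (no hinge products), which is the standard default for tabular
bioprocess data at these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MarsModel"]


@dataclass(frozen=True)
class _Hinge:
    var: int
    knot: float
    positive: bool  # max(x - k, 0) if True else max(k - x, 0)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        x = X[:, self.var]
        return np.maximum(x - self.knot, 0.0) if self.positive else np.maximum(self.knot - x, 0.0)


@dataclass
class MarsModel:
    """MARS regression with forward selection and GCV pruning.

    Parameters
    ----------
    max_terms
        Upper bound on basis functions (including the intercept) grown in
        the forward pass.
    max_knots
        Candidate knots per variable (quantiles of the observed values).
    penalty
        GCV cost per knot.
    min_improvement
        Forward pass stops when the relative residual-sum-of-squares
        improvement falls below this.
    """

    max_terms: int = 21
    max_knots: int = 12
    penalty: float = 3.0
    min_improvement: float = 1e-8

    basis_: list[_Hinge] = field(default_factory=list, init=False, repr=False)
    coef_: np.ndarray | None = field(default=None, init=False, repr=False)
    intercept_: float = field(default=0.0, init=False, repr=False)
    gcv_: float = field(default=np.inf, init=False, repr=False)

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MarsModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, d) with matching y")
        n, d = X.shape
        if n < 4:
            raise ValueError("need at least 4 observations")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("MARS requires finite inputs (impute first)")

        candidates = self._candidate_hinges(X)
        basis = self._forward_pass(X, y, candidates)
        self.basis_, self.gcv_ = self._prune(X, y, basis)
        B = self._design(X, self.basis_)
        coefs, *_ = np.linalg.lstsq(B, y, rcond=None)
        self.intercept_ = float(coefs[0])
        self.coef_ = coefs[1:]
        return self

    def _candidate_hinges(self, X: np.ndarray) -> list[_Hinge]:
        out: list[_Hinge] = []
        n, d = X.shape
        for j in range(d):
            uniq = np.unique(X[:, j])
            if uniq.size < 3:
                continue
            if uniq.size <= self.max_knots:
                knots = uniq[1:-1]
            else:
                qs = np.linspace(0.05, 0.95, self.max_knots)
                knots = np.unique(np.quantile(X[:, j], qs))
            for k in knots:
                out.append(_Hinge(j, float(k), True))
        return out

    def _forward_pass(
        self, X: np.ndarray, y: np.ndarray, candidates: list[_Hinge]
    ) -> list[_Hinge]:
        n = X.shape[0]
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0 or not candidates:
            return []
        # columns for all mirrored pairs, computed once
        pos_cols = np.stack([h.evaluate(X) for h in candidates], axis=1)
        neg_cols = np.stack(
            [_Hinge(h.var, h.knot, False).evaluate(X) for h in candidates], axis=1
        )

        basis: list[_Hinge] = []
        B = np.ones((n, 1))
        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        rss = float(r @ r)
        while len(basis) + 2 < self.max_terms:
            Cp = pos_cols - Q @ (Q.T @ pos_cols)
            Cn = neg_cols - Q @ (Q.T @ neg_cols)
            bp = Cp.T @ r
            bn = Cn.T @ r
            gpp = np.einsum("ij,ij->j", Cp, Cp)
            gnn = np.einsum("ij,ij->j", Cn, Cn)
            gpn = np.einsum("ij,ij->j", Cp, Cn)
            det = gpp * gnn - gpn**2
            eps = 1e-12 * max(sst, 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                red_pair = np.where(
                    det > eps,
                    (gnn * bp**2 - 2 * gpn * bp * bn + gpp * bn**2) / det,
                    0.0,
                )
                red_pos = np.where(gpp > eps, bp**2 / gpp, 0.0)
                red_neg = np.where(gnn > eps, bn**2 / gnn, 0.0)
            reduction = np.maximum(red_pair, np.maximum(red_pos, red_neg))
            best = int(np.argmax(reduction))
            if reduction[best] <= self.min_improvement * sst:
                break
            h = candidates[best]
            new = []
            if red_pair[best] >= max(red_pos[best], red_neg[best]):
                new = [h, _Hinge(h.var, h.knot, False)]
            elif red_pos[best] >= red_neg[best]:
                new = [h]
            else:
                new = [_Hinge(h.var, h.knot, False)]
            basis.extend(new)
            B = self._design(X, basis)
            Q, _ = np.linalg.qr(B)
            r = y - Q @ (Q.T @ y)
            new_rss = float(r @ r)
            if rss - new_rss <= self.min_improvement * sst:
                basis = basis[: len(basis) - len(new)]
                break
            rss = new_rss
        return basis

    def _gcv(self, rss: float, n: int, n_terms: int) -> float:
        c = n_terms + self.penalty * (n_terms - 1) / 2.0
        if c >= n:
            return np.inf
        return (rss / n) / (1.0 - c / n) ** 2

    def _prune(
        self, X: np.ndarray, y: np.ndarray, basis: list[_Hinge]
    ) -> tuple[list[_Hinge], float]:
        n = X.shape[0]

        def rss_of(sub: list[_Hinge]) -> float:
            B = self._design(X, sub)
            coefs, *_ = np.linalg.lstsq(B, y, rcond=None)
            resid = y - B @ coefs
            return float(resid @ resid)

        current = list(basis)
        best_set = list(current)
        best_gcv = self._gcv(rss_of(current), n, len(current) + 1)
        while current:
            trial_scores = []
            for i in range(len(current)):
                sub = current[:i] + current[i + 1 :]
                trial_scores.append(self._gcv(rss_of(sub), n, len(sub) + 1))
            i_best = int(np.argmin(trial_scores))
            current = current[:i_best] + current[i_best + 1 :]
            if trial_scores[i_best] <= best_gcv:
                best_gcv = trial_scores[i_best]
                best_set = list(current)
        return best_set, best_gcv

    @staticmethod
    def _design(X: np.ndarray, basis: list[_Hinge]) -> np.ndarray:
        cols = [np.ones(X.shape[0])]
        cols.extend(h.evaluate(X) for h in basis)
        return np.stack(cols, axis=1)

    # -- inference ----------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        B = self._design(X, self.basis_)
        return B @ np.concatenate([[self.intercept_], self.coef_])

    @property
    def selected_variables(self) -> list[int]:
        """Indices of variables appearing in at least one retained basis
        function, in order of first appearance."""
        seen: list[int] = []
        for h in self.basis_:
            if h.var not in seen:
                seen.append(h.var)
        return seen

    def basis_count_per_variable(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for h in self.basis_:
            counts[h.var] = counts.get(h.var, 0) + 1
        return counts
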