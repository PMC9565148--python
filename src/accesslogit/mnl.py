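"""Multinomial-logit destination choice: maximum likelihood with inference.

The model: a visitor in zone *i* choosing destination *j* from choice set
*J* receives utility

    V_ij = beta * t_ij + X_j @ gamma,

with t_ij a travel impedance (car minutes or a mode-choice logsum) and X_j
destination attributes, and chooses with probability

    P_ij = exp(V_ij) / sum_{j' in J} exp(V_ij').

Estimation maximises sum(log P over chosen alternatives) by Newton–Raphson
with analytic score and Hessian, falling back to BFGS when the Hessian is
not positive definite.  Standard errors come from the observed information
at the optimum (no sandwich correction).  The null log-likelihood is the
equal-shares model over each observation's alternative-set size, which is
also the normalisation used by McFadden's rho-squared.

Also provided: the Horowitz / Ben-Akiva–Swait bound for comparing two
non-nested specifications fitted to the same observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from scipy.stats import norm

from .choicedata import ChoiceDataset, ModelSpec

__all__ = [
    "DestinationChoiceModel",
    "DestinationChoiceResults",
    "choice_probabilities",
    "mcfadden_rho",
    "horowitz_test",
    "NonIdentifiedError",
    "ConvergenceError",
]


class NonIdentifiedError(ValueError):
    """A covariate cannot be identified (constant within every choice set)."""


class ConvergenceError(RuntimeError):
    """Optimisation diverged — typically perfect separation."""


def choice_probabilities(coef: np.ndarray, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Choice probabilities for covariate array(s) ``X``.

    ``X`` has shape (J, K) for one observation or (n, J, K) for a batch;
    ``mask`` (same leading shape, J) marks valid alternatives.  Computed
    with max-shift stabilisation; rows sum to one.
    """
    coef = np.asarray(coef, dtype=float)
    X = np.asarray(X, dtype=float)
    V = X @ coef
    if mask is not None:
        V = np.where(mask, V, -np.inf)
    return softmax(V, axis=-1)


def mcfadden_rho(loglik: float, n_obs: int, n_alt: int) -> float:
    """McFadden rho-squared against the equal-shares null:
    ``1 - loglik / (n_obs * ln(1/n_alt))``."""
    if n_obs < 1 or n_alt < 1:
        raise ValueError("n_obs and n_alt must be at least 1")
    return 1.0 - loglik / (n_obs * np.log(1.0 / n_alt))


class DestinationChoiceModel:
    """Multinomial-logit destination-choice model on a long-format dataset.

    Parameters
    ----------
    dataset : ChoiceDataset
        Long frame with obs_id / resource_id / chosen plus covariates.
    covariates : optional list of covariate column names; defaults to the
        dataset spec's covariate names.
    """

    def __init__(
        self,
        dataset: ChoiceDataset,
        covariates: Sequence[str] | None = None,
        drop_unidentified: bool = False,
    ):
        self.dataset = dataset
        self.spec: ModelSpec = dataset.spec
        self.covariate_names = list(covariates or self.spec.covariate_names)
        self._drop_unidentified = drop_unidentified
        self._build_arrays(dataset.df)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: Sequence[str],
        spec: ModelSpec | None = None,
        obs_col: str = "obs_id",
        chosen_col: str = "chosen",
    ) -> "DestinationChoiceModel":
        """Build directly from a long DataFrame without a ModelSpec."""
        obj = cls.__new__(cls)
        obj.dataset = None
        obj.spec = spec
        obj.covariate_names = list(covariates)
        obj._drop_unidentified = False
        obj._build_arrays(df, obs_col=obs_col, chosen_col=chosen_col)
        return obj

    # ------------------------------------------------------------------
    def _build_arrays(self, df: pd.DataFrame, obs_col: str = "obs_id", chosen_col: str = "chosen") -> None:
        if df.empty:
            raise ValueError("empty dataset")
        df = df.sort_values(obs_col, kind="stable")
        sizes = df.groupby(obs_col, sort=False).size()
        n_obs, j_max, k = len(sizes), int(sizes.max()), len(self.covariate_names)

        X = np.zeros((n_obs, j_max, k))
        mask = np.zeros((n_obs, j_max), dtype=bool)
        chosen = np.zeros(n_obs, dtype=int)

        row_obs = np.repeat(np.arange(n_obs), sizes.to_numpy())
        row_alt = np.concatenate([np.arange(s) for s in sizes.to_numpy()])
        cov = df[self.covariate_names].to_numpy(dtype=float)
        if not np.isfinite(cov).all():
            raise ValueError("non-finite covariate values; drop such observations upstream")
        X[row_obs, row_alt] = cov
        mask[row_obs, row_alt] = True
        ch = df[chosen_col].to_numpy(dtype=bool)
        if not np.all(np.bincount(row_obs, weights=ch) == 1):
            raise ValueError("each observation must have exactly one chosen alternative")
        chosen[row_obs[ch]] = row_alt[ch]

        self.X, self.mask, self.chosen = X, mask, chosen
        self.n_obs, self.j_max, self.k = n_obs, j_max, k
        self.n_alt_sizes = sizes.to_numpy()
        self._check_identification()

    def _check_identification(self) -> None:
        # A covariate constant within every observation differences out of
        # the logit and cannot be estimated.
        X, mask = self.X, self.mask
        constant = []
        for k, name in enumerate(self.covariate_names):
            vals = X[..., k]
            ref = np.take_along_axis(vals, np.argmax(mask, axis=1)[:, None], axis=1)
            if np.all((vals == ref) | ~mask):
                constant.append((k, name))
        if not constant:
            return
        names = [n for _, n in constant]
        if not self._drop_unidentified:
            raise NonIdentifiedError(
                f"covariate(s) {names} are constant within every choice set; "
                "they difference out of the logit and are not identified"
            )
        import logging

        logging.getLogger(__name__).warning(
            "dropping unidentified covariate(s) %s (constant within every choice set)",
            names,
        )
        keep = [k for k in range(self.k) if k not in {k0 for k0, _ in constant}]
        if not keep:
            raise NonIdentifiedError("no identifiable covariates remain")
        self.X = self.X[..., keep]
        self.covariate_names = [self.covariate_names[k] for k in keep]
        self.k = len(keep)

    # ------------------------------------------------------------------
    def utilities(self, params: np.ndarray) -> np.ndarray:
        V = self.X @ np.asarray(params, dtype=float)
        return np.where(self.mask, V, -np.inf)

    def probabilities(self, params: np.ndarray) -> np.ndarray:
        """(n_obs, j_max) choice probabilities; zero on padded slots."""
        return softmax(self.utilities(params), axis=1)

    def loglike(self, params: np.ndarray) -> float:
        V = self.utilities(params)
        return float(np.sum(V[np.arange(self.n_obs), self.chosen] - logsumexp(V, axis=1)))

    def score(self, params: np.ndarray) -> np.ndarray:
        P = self.probabilities(params)
        x_chosen = self.X[np.arange(self.n_obs), self.chosen]
        x_bar = np.einsum("nj,njk->nk", P, self.X)
        return (x_chosen - x_bar).sum(axis=0)

    def hessian(self, params: np.ndarray) -> np.ndarray:
        P = self.probabilities(params)
        x_bar = np.einsum("nj,njk->nk", P, self.X)
        ExxT = np.einsum("nj,njk,njl->kl", P, self.X, self.X)
        return -(ExxT - x_bar.T @ x_bar)

    @property
    def llnull(self) -> float:
        """Equal-shares log-likelihood: sum over observations of ln(1/J_i)."""
        return float(np.sum(np.log(1.0 / self.n_alt_sizes)))

    # ------------------------------------------------------------------
    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 100,
        gtol: float = 1e-6,
        coef_bound: float = 1e4,
    ) -> "DestinationChoiceResults":
        """Maximise the likelihood; converged when ``max |score| < gtol``.

        Newton–Raphson with step halving; a non-positive-definite Hessian
        triggers a BFGS fallback.  A coefficient norm exceeding
        ``coef_bound`` is treated as divergence (perfect separation).
        """
        beta = np.zeros(self.k) if start is None else np.asarray(start, dtype=float)
        ll = self.loglike(beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            g = self.score(beta)
            if np.max(np.abs(g)) < gtol:
                converged = True
                break
            H = self.hessian(beta)
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                beta = self._fit_bfgs(beta)
                g = self.score(beta)
                converged = np.max(np.abs(g)) < gtol
                break
            # step halving against likelihood decrease
            alpha = 1.0
            for _ in range(30):
                cand = beta + alpha * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                alpha *= 0.5
            beta, ll = cand, ll_new
            if np.linalg.norm(beta) > coef_bound:
                raise ConvergenceError(
                    "coefficients diverged (norm > %g); a covariate may perfectly "
                    "predict the choice (separation)" % coef_bound
                )
        else:
            g = self.score(beta)
            converged = np.max(np.abs(g)) < gtol

        # Perfect separation drives every chosen probability to one along a
        # direction of unbounded likelihood; the optimiser then stalls on a
        # flat ridge rather than blowing up, so detect it at the "optimum".
        p_chosen = self.probabilities(beta)[np.arange(self.n_obs), self.chosen]
        if np.all(p_chosen > 1 - 1e-6):
            raise ConvergenceError(
                "likelihood is unbounded: the covariates perfectly predict every "
                "choice (separation); coefficients are not estimable"
            )
        H = self.hessian(beta)
        try:
            vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(-H)
        return DestinationChoiceResults(self, beta, vcov, converged=converged, n_iter=n_iter)

    def _fit_bfgs(self, start: np.ndarray) -> np.ndarray:
        from scipy.optimize import minimize

        res = minimize(
            lambda b: -self.loglike(b),
            start,
            jac=lambda b: -self.score(b),
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        return res.x


@dataclass
class DestinationChoiceResults:
    """Fitted destination-choice model: estimates, inference, fit statistics."""

    model: DestinationChoiceModel
    _params: np.ndarray
    _vcov: np.ndarray
    converged: bool = True
    n_iter: int = 0

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.covariate_names, name="coef")

    @property
    def cov_params(self) -> pd.DataFrame:
        names = self.model.covariate_names
        return pd.DataFrame(self._vcov, index=names, columns=names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._vcov)), index=self.model.covariate_names, name="se")

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def llf(self) -> float:
        return self.model.loglike(self._params)

    @property
    def llnull(self) -> float:
        return self.model.llnull

    @property
    def nobs(self) -> int:
        return self.model.n_obs

    @property
    def n_alt(self) -> int:
        return int(self.model.n_alt_sizes.max())

    @property
    def df_model(self) -> int:
        return self.model.k

    @property
    def rho_squared(self) -> float:
        return 1.0 - self.llf / self.llnull

    @property
    def rho_squared_adj(self) -> float:
        """Adjusted rho-squared, ``1 - (llf - K)/llnull``."""
        return 1.0 - (self.llf - self.df_model) / self.llnull

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "lower": self.params - z * self.bse,
            "upper": self.params + z * self.bse,
        })

    def summary(self) -> str:
        """Estimation report: coefficient (t-statistic), Num.Obs.,
        Log Likelihood, McFadden Rho-Sq."""
        lines = ["Destination choice model (multinomial logit)"]
        if self.model.spec is not None:
            lines[0] += f" — rtype={self.model.spec.rtype}, impedance={self.model.spec.impedance_kind}"
        lines.append("=" * 58)
        for name in self.model.covariate_names:
            lines.append(
                f"{name:<24s} {self.params[name]: 10.3f}  ({self.tvalues[name]: .3f})"
            )
        lines.append("-" * 58)
        lines.append(f"{'Num.Obs.':<24s} {self.nobs:d}")
        lines.append(f"{'Log Likelihood':<24s} {self.llf:.1f}")
        lines.append(f"{'McFadden Rho-Sq':<24s} {self.rho_squared:.3f}")
        if not self.converged:
            lines.append("WARNING: optimiser did not converge")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        """Machine-readable coefficient file for the accessibility stage."""
        import json

        payload = {
            "covariates": self.model.covariate_names,
            "coef": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "loglik": self.llf,
            "loglik_null": self.llnull,
            "n_obs": self.nobs,
            "n_alt": self.n_alt,
            "rho_squared": self.rho_squared,
            "converged": bool(self.converged),
        }
        if self.model.spec is not None:
            fitted = set(self.model.covariate_names)
            terms = [
                [name, transform]
                for name, transform in self.model.spec.attribute_terms
                if (f"log_{name}" if transform == "log" else name) in fitted
            ]
            payload["spec"] = {
                "rtype": self.model.spec.rtype,
                "impedance_kind": self.model.spec.impedance_kind,
                "attribute_terms": terms,
            }
        Path(path).write_text(json.dumps(payload, indent=2))


def horowitz_test(low: "DestinationChoiceResults | tuple", high: "DestinationChoiceResults | tuple", llnull: float | None = None) -> float:
    """Upper-bound p-value for comparing two non-nested specifications
    fitted to the same observations (Horowitz; Ben-Akiva–Swait form).

    With adjusted rho-squared difference ``z = rho_adj_high - rho_adj_low``
    (adjusted: ``1 - (ll - K)/llnull``), the probability that the
    lower-fit model is nevertheless the true one is bounded by

        p <= Phi( -sqrt( -2 z llnull + (K_high - K_low) ) ).

    Arguments may be results objects or ``(loglik, K)`` tuples with
    ``llnull`` supplied.  Raises if ``z < 0`` (order the models first).
    """
    def unpack(m):
        if isinstance(m, DestinationChoiceResults):
            return m.llf, m.df_model, m.llnull
        ll, k = m
        return ll, k, llnull

    ll_l, k_l, null_l = unpack(low)
    ll_h, k_h, null_h = unpack(high)
    if null_l is None or null_h is None:
        raise ValueError("llnull required when passing (loglik, K) tuples")
    if not np.isclose(null_l, null_h):
        raise ValueError("models must share the same null log-likelihood (same dataset)")
    ll0 = null_h
    z = ((ll_h - k_h) - (ll_l - k_l)) / (-ll0)  # rho_adj_high - rho_adj_low
    if z < -1e-12:
        raise ValueError("model_high must have the higher adjusted rho-squared")
    z = max(z, 0.0)
    stat = -2.0 * z * ll0 + (k_h - k_l)
    return float(norm.cdf(-np.sqrt(max(stat, 0.0))))
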