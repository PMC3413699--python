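"""Two-step binomial logistic regression for assay-outcome prediction.

Two binary outcomes describe what happens when a candidate SNP meets the
genotyping chemistry: *conversion* (did the assay amplify and cluster) and,
among converted assays only, *polymorphism* (did it segregate). Nine
pipeline variables serve as predictors: ascertainment individuals with
reads at the site, read depth at the site, minor-allele read count,
minor-allele read fraction, ascertainment individuals carrying the minor
allele, the Assay Design Score, the intron–exon boundary outcome (two
dummies against the no-match reference level), the number of reference
species supporting that outcome, and the neighbourhood sequence quality.

Fitting is maximum likelihood via iteratively reweighted least squares
(Newton scoring), converged when the relative log-likelihood change drops
below 1e-10 (at most 100 iterations); standard errors come from the
observed information matrix. Each term's Wald statistic is (B/SE)^2 with a
chi-square(1) p-value, and backward stepwise elimination removes the term
with the largest Wald p >= p_remove (default 0.10, the classic stepwise
default) until only contributing terms remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

PREDICTOR_TERMS = [
    "asc_ind_reads", "n_reads_at_snp", "n_minor_reads", "minor_freq",
    "asc_ind_minor", "ads", "boundary_single", "boundary_intron",
    "n_supporting_species", "nsq",
]

# reduced a priori set: depth, minor fraction, neighbourhood quality, design
# score, and the boundary outcome dummies
REDUCED_TERMS = ["n_reads_at_snp", "minor_freq", "nsq", "ads",
                 "boundary_single", "boundary_intron"]


class SeparationError(RuntimeError):
    """Raised when the outcome is completely separated by the predictors."""


@dataclass
class RegressionFit:
    terms: list[str]                    # without the constant
    coefficients: pd.Series             # includes 'constant'
    std_errors: pd.Series
    wald: pd.Series                     # (B/SE)^2
    p_values: pd.Series                 # chi2(1) upper tail
    log_likelihood: float
    null_log_likelihood: float
    n: int
    converged: bool

    @property
    def model_chi2(self) -> float:
        """Likelihood-ratio statistic of the fitted model against the null."""
        return 2.0 * (self.log_likelihood - self.null_log_likelihood)

    @property
    def model_df(self) -> int:
        return len(self.terms)

    @property
    def model_p(self) -> float:
        if self.model_df == 0:
            return 1.0
        return float(chi2.sf(self.model_chi2, self.model_df))

    def table(self) -> pd.DataFrame:
        """Per-term report: B, Wald, df, P (constant last)."""
        order = self.terms + ["constant"]
        return pd.DataFrame({
            "B": self.coefficients[order].round(3),
            "Wald": self.wald[order].round(3),
            "df": 1,
            "P": self.p_values[order].round(3),
        })


def assemble_predictors(snp_table: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Join pipeline outputs with assay outcomes into the predictor table.

    ``snp_table`` needs: contig_id, position, individuals_covering, depth,
    minor_count, individuals_with_minor, ads, boundary, supporting_species,
    nsq. ``outcomes`` needs: contig_id, position, conversion (0/1) and
    optionally polymorphism (0/1, only meaningful where conversion == 1).
    The boundary outcome becomes two dummies against the no-match reference.
    """
    df = snp_table.merge(outcomes, on=["contig_id", "position"], how="inner")
    out = pd.DataFrame({
        "contig_id": df.contig_id,
        "position": df.position,
        "asc_ind_reads": df.individuals_covering.astype(float),
        "n_reads_at_snp": df.depth.astype(float),
        "n_minor_reads": df.minor_count.astype(float),
        "minor_freq": df.minor_count / df.depth,
        "asc_ind_minor": df.individuals_with_minor.astype(float),
        "ads": df.ads.astype(float),
        "boundary_single": (df.boundary.astype(str) == "single_exon").astype(float),
        "boundary_intron": (df.boundary.astype(str) == "boundary").astype(float),
        "n_supporting_species": df.supporting_species.astype(float),
        "nsq": df.nsq.astype(float),
        "conversion": df.conversion.astype(int),
    })
    if "polymorphism" in df:
        poly = df.polymorphism.astype(float)
        poly[out.conversion == 0] = np.nan      # undefined for failed assays
        out["polymorphism"] = poly
    out["missing_predictor"] = out[PREDICTOR_TERMS].isna().any(axis=1)
    return out


def _irls(x: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100,
          ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """IRLS for the binomial logit. Returns (beta, cov, loglik, converged)."""
    n, k = x.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                          (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-30):
            converged = True
            break
        ll_old = ll
        w = mu * (1.0 - mu)
        if np.all((mu[y == 1] > 1 - 1e-9) if (y == 1).any() else True) and \
           np.all((mu[y == 0] < 1e-9) if (y == 0).any() else True):
            raise SeparationError("complete separation: likelihood is unbounded")
        xtw = x.T * w
        hess = xtw @ x
        try:
            step = np.linalg.solve(hess, x.T @ (y - mu))
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"singular information matrix: {err}") from err
        beta = beta + step
        if np.abs(beta).max() > 1e4:
            raise SeparationError("diverging coefficients: separation suspected")
    if not converged and np.abs(beta).max() > 50:
        raise SeparationError("no convergence with runaway coefficients")
    eta = np.clip(x @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                      (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    w = mu * (1.0 - mu)
    hess = (x.T * w) @ x
    cov = np.linalg.inv(hess)
    return beta, cov, ll, converged


def logistic_fit(table: pd.DataFrame, outcome: str, terms: list[str],
                 ) -> RegressionFit:
    """Fit a binomial logistic regression of ``outcome`` on ``terms``.

    Rows with missing values among the used columns are excluded; complete
    separation raises :class:`SeparationError` rather than silently
    diverging.
    """
    cols = list(terms) + [outcome]
    data = table[cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome} must be binary 0/1")
    x = np.column_stack([data[t].to_numpy(dtype=float) for t in terms]
                        + [np.ones(len(data))])
    names = list(terms) + ["constant"]
    beta, cov, ll, converged = _irls(x, y)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    pvals = chi2.sf(wald, df=1)
    # null model: intercept only, closed form
    k = float(y.sum())
    n = float(len(y))
    if k in (0.0, n):
        ll_null = 0.0
    else:
        p0 = k / n
        ll_null = float(k * np.log(p0) + (n - k) * np.log(1 - p0))
    return RegressionFit(
        terms=list(terms),
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        wald=pd.Series(wald, index=names),
        p_values=pd.Series(pvals, index=names),
        log_likelihood=ll,
        null_log_likelihood=ll_null,
        n=int(n),
        converged=converged,
    )


def backward_eliminate(table: pd.DataFrame, outcome: str, terms: list[str],
                       p_remove: float = 0.10,
                       ) -> tuple[RegressionFit, list[dict]]:
    """Backward stepwise elimination on Wald p-values.

    Repeatedly drops the term with the largest Wald p >= ``p_remove`` and
    refits, until every remaining term contributes (p < p_remove) or none
    remain. Deterministic: no randomness, ties broken by term order.
    Returns the final fit and the elimination trace.
    """
    current = list(terms)
    trace: list[dict] = []
    fit = logistic_fit(table, outcome, current)
    while current:
        p_terms = fit.p_values[current]
        worst = p_terms.idxmax()
        if p_terms[worst] < p_remove:
            break
        trace.append({"removed": worst, "p": float(p_terms[worst]),
                      "remaining": [t for t in current if t != worst]})
        current = [t for t in current if t != worst]
        fit = logistic_fit(table, outcome, current)
    return fit, trace


def simulate_validation_outcomes(predictors: pd.DataFrame,
                                 coef: dict[str, float] | None = None,
                                 seed: int = 0) -> pd.DataFrame:
    """Draw synthetic conversion/polymorphism outcomes from a logistic model.

    Default effects echo the direction of the reported associations: design
    score helps conversion; neighbourhood noise hurts polymorphism.
    """
    rng = np.random.default_rng(seed)
    coef = coef or {"ads": 1.5, "asc_ind_minor": -0.15, "constant": -0.5}
    eta = np.full(len(predictors), coef.get("constant", 0.0))
    for term, b in coef.items():
        if term != "constant" and term in predictors:
            eta = eta + b * predictors[term].to_numpy(dtype=float)
    conv = (rng.uniform(size=len(eta)) < 1 / (1 + np.exp(-eta))).astype(int)
    eta_poly = 0.9 - 0.12 * predictors["nsq"].to_numpy(dtype=float)
    poly = (rng.uniform(size=len(eta)) < 1 / (1 + np.exp(-eta_poly))).astype(float)
    poly[conv == 0] = np.nan
    out = predictors.copy()
    out["conversion"] = conv
    out["polymorphism"] = poly
    return out
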