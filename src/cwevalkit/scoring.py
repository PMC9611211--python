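"""Factor-analysis-weighted composite treatment-efficiency scoring.

Six pollutant removal rates (COD, TP, TN, NO3-N, NH4-N and an antibiotic)
are correlated, so a composite score built from a simple mean would double
count shared variance.  The procedure implemented here derives indicator
weights from a factor analysis of the removal-rate correlation matrix:

1. Pearson correlation matrix R of the removal indicators, with KMO
   sampling adequacy and Bartlett sphericity as applicability diagnostics.
2. Eigendecomposition of R; factors retained by the Kaiser criterion
   (eigenvalue > 1) or a fixed k; unrotated loading column j is
   ``eigvec_j * sqrt(lambda_j)``.
3. Varimax rotation of the retained loadings.
4. Factor weights ``T_j`` = share of post-rotation explained variance
   (column sums of squared rotated loadings, normalised to 1).
5. Indicator weights ``B_i`` = sum_j T_j * (l_ij / sum_i l_ij), i.e. the
   factor weights distributed over indicators by within-factor
   L1-normalised loadings; the B_i sum to 1.
6. Composite score ``E = sum_i A_i * B_i`` for removal fractions A_i, one
   score per (system, day).

Use :class:`CompositeEfficiencyModel` for the statsmodels-style fit
interface, or the individual functions for the pieces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import validate_removal_table

__all__ = [
    "CorrelationMatrix",
    "FactorModel",
    "correlation_matrix",
    "kmo",
    "bartlett",
    "extract_factors",
    "varimax",
    "varimax_criterion",
    "factor_weights",
    "indicator_weights",
    "composite_score",
    "tucker_congruence",
    "CompositeEfficiencyModel",
    "CompositeEfficiencyResults",
    "score_pipeline",
]


@dataclass
class CorrelationMatrix:
    """Indicator Pearson correlation matrix plus the observation count."""

    labels: list
    values: np.ndarray
    n_obs: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if self.values.shape != (p, p):
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.values).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _observation_matrix(removal: pd.DataFrame, aggregate: str) -> pd.DataFrame:
    """Pivot a long removal table to observations x pollutants.

    ``aggregate='replicate_mean'`` averages replicates so each (system, day)
    is one observation; ``aggregate='none'`` keeps every replicate as its
    own observation.
    """
    removal = validate_removal_table(removal)
    if aggregate == "replicate_mean":
        index = ["system", "day"]
        values = removal.groupby(index + ["pollutant"], sort=False)["removal"].mean()
        wide = values.unstack("pollutant")
    elif aggregate == "none":
        wide = removal.pivot(
            index=["system", "day", "replicate"], columns="pollutant",
            values="removal",
        )
    else:
        raise ValueError(f"unknown aggregate policy {aggregate!r}")
    return wide.dropna(axis=0)


def correlation_matrix(
    removal: pd.DataFrame, aggregate: str = "replicate_mean"
) -> CorrelationMatrix:
    """Pearson correlations between pollutant removal indicators."""
    wide = _observation_matrix(removal, aggregate)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 pollutant indicators")
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 observation rows after aggregation")
    sd = wide.std(axis=0, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        raise ValueError(
            f"constant indicator(s) {list(constant)}: correlation undefined"
        )
    corr = np.corrcoef(wide.to_numpy(), rowvar=False)
    # clamp tiny negative eigenvalues from floating point
    return CorrelationMatrix(list(wide.columns), corr, n_obs=wide.shape[0])


def kmo(corr: CorrelationMatrix | np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are
    the anti-image (partial) correlations obtained from the inverse of the
    correlation matrix.  Values above ~0.6 conventionally justify factor
    analysis.
    """
    R = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; drop a collinear indicator"
        ) from exc
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett(corr: CorrelationMatrix | np.ndarray, n_obs: int | None = None):
    """Bartlett's sphericity test that R differs from the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det R with df = p(p-1)/2.
    Returns ``(chi2, df, p_value)``.
    """
    if isinstance(corr, CorrelationMatrix):
        R = corr.values
        n_obs = corr.n_obs if n_obs is None else n_obs
    else:
        R = np.asarray(corr)
        if n_obs is None:
            raise ValueError("n_obs is required with a bare matrix")
    p = R.shape[0]
    if n_obs <= p:
        raise ValueError("need more observations than indicators")
    det = np.linalg.det(R)
    if det <= 0:
        raise ValueError("correlation matrix determinant is not positive")
    chi2 = -(n_obs - 1 - (2 * p + 5) / 6) * np.log(det)
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def _fix_signs(L: np.ndarray) -> np.ndarray:
    """Flip loading columns so each column's largest-|entry| is positive.

    Ties are broken by the first index.
    """
    L = L.copy()
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


@dataclass
class FactorModel:
    """Eigenstructure and loadings of an indicator correlation matrix."""

    labels: list
    eigenvalues: np.ndarray          # all p, descending
    k: int                           # number of retained factors
    loadings: np.ndarray             # p x k, unrotated
    loadings_rotated: np.ndarray     # p x k, after varimax
    n_obs: int | None = None

    @property
    def variance_pct(self) -> np.ndarray:
        return self.eigenvalues / len(self.labels) * 100.0

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.variance_pct)

    @property
    def ss_loadings_rotated(self) -> np.ndarray:
        return (self.loadings_rotated ** 2).sum(axis=0)

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings_rotated ** 2).sum(axis=1)

    def variance_table(self) -> pd.DataFrame:
        """Eigenvalues with percent and cumulative percent of variance."""
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "variance_pct": self.variance_pct,
                "cumulative_pct": self.cumulative_pct,
            }
        )

    def loadings_frame(self, rotated: bool = True) -> pd.DataFrame:
        L = self.loadings_rotated if rotated else self.loadings
        cols = [f"factor{j + 1}" for j in range(self.k)]
        return pd.DataFrame(L, index=self.labels, columns=cols)


def extract_factors(
    corr: CorrelationMatrix, retain="kaiser"
) -> FactorModel:
    """Principal-component factor extraction with varimax rotation.

    ``retain`` is ``'kaiser'`` (eigenvalue > 1) or an integer k >= 1.
    """
    R = corr.values
    p = R.shape[0]
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    if retain == "kaiser":
        k = int(np.sum(eigval > 1.0))
    else:
        k = int(retain)
    if k < 1:
        raise ValueError(
            "factor retention selected 0 factors (no eigenvalue > 1); "
            "pass a fixed k instead"
        )
    if k > p:
        raise ValueError("cannot retain more factors than indicators")

    loadings = _fix_signs(eigvec[:, :k] * np.sqrt(eigval[:k]))
    rotated = varimax(loadings) if k > 1 else loadings.copy()
    return FactorModel(
        labels=list(corr.labels),
        eigenvalues=eigval,
        k=k,
        loadings=loadings,
        loadings_rotated=rotated,
        n_obs=corr.n_obs,
    )


def varimax_criterion(L: np.ndarray) -> float:
    """Unnormalised varimax criterion: sum_j [sum_i l^4 - (sum_i l^2)^2 / p]."""
    L = np.asarray(L, dtype=float)
    p = L.shape[0]
    sq = L ** 2
    return float(np.sum(sq ** 2) - np.sum(sq.sum(axis=0) ** 2) / p)


def varimax(
    L: np.ndarray, tol: float = 1e-12, max_iter: int = 100,
    row_normalize: bool = False,
) -> np.ndarray:
    """Orthogonal varimax rotation of a p x k loading matrix.

    Kaiser's pairwise algorithm: every column pair is rotated by the
    closed-form angle phi = atan2(D - 2AB/p, C - (A^2 - B^2)/p) / 4
    maximising the pair's contribution to the unnormalised varimax
    criterion; sweeps repeat until the largest rotation angle falls below
    ``tol``.  Kaiser row normalisation is off by default (``row_normalize``
    enables it).  Columns of the result are ordered by descending sum of
    squared loadings and sign-fixed so each column's largest-|entry| is
    positive.  ``k = 1`` returns the sign-fixed input.
    """
    L = np.asarray(L, dtype=float).copy()
    p, k = L.shape
    if k == 1:
        return _fix_signs(L)

    norms = None
    if row_normalize:
        norms = np.sqrt((L ** 2).sum(axis=1, keepdims=True))
        norms[norms == 0] = 1.0
        L = L / norms

    converged = False
    for _ in range(max_iter):
        max_angle = 0.0
        for j in range(k - 1):
            for l in range(j + 1, k):
                x, y = L[:, j].copy(), L[:, l].copy()
                u = x * x - y * y
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = (u * u - v * v).sum()
                D = 2.0 * (u * v).sum()
                phi = 0.25 * np.arctan2(
                    D - 2.0 * A * B / p, C - (A * A - B * B) / p
                )
                if abs(phi) > 1e-15:
                    c, s = np.cos(phi), np.sin(phi)
                    L[:, j] = c * x + s * y
                    L[:, l] = -s * x + c * y
                max_angle = max(max_angle, abs(phi))
        if max_angle < tol:
            converged = True
            break
    if not converged:
        warnings.warn("varimax did not converge; returning best iterate")

    if row_normalize:
        L = L * norms
    order = np.argsort((L ** 2).sum(axis=0))[::-1]
    return _fix_signs(L[:, order])


def _rotated_loadings(m) -> np.ndarray:
    if isinstance(m, FactorModel):
        return np.asarray(m.loadings_rotated, dtype=float)
    return np.asarray(m, dtype=float)


def factor_weights(m: FactorModel | np.ndarray) -> np.ndarray:
    """Factor weights T_j from post-rotation explained-variance shares.

    T_j = SS_j / sum SS, where SS_j is the column sum of squared rotated
    loadings.  Accepts a :class:`FactorModel` or a bare rotated p x k
    loading matrix.
    """
    L = _rotated_loadings(m)
    ss = (L ** 2).sum(axis=0)
    total = ss.sum()
    if total <= 0:
        raise ValueError("all-zero loading matrix")
    return ss / total


def indicator_weights(
    m: FactorModel | np.ndarray,
    T: np.ndarray | None = None,
    combination: str = "normalized",
) -> np.ndarray:
    """Final per-indicator weights B_i combining loadings and factor weights.

    ``combination='normalized'`` (default): each loading is divided by its
    factor's column sum (within-factor L1 share), then the shares are mixed
    with the factor weights: B_i = sum_j T_j * l_ij / sum_i l_ij.  The B_i
    sum to 1 exactly.

    ``combination='literal'``: B_i proportional to sum_j T_j * l_ij (the
    loadings mixed directly), L1-normalised so the weights still sum to 1.

    Negative loadings (possible after sign-fixing when an indicator opposes
    a factor) trigger a warning and are used in absolute value.
    """
    L = _rotated_loadings(m)
    if T is None:
        T = factor_weights(L)
    T = np.asarray(T, dtype=float)
    if L.shape[1] != T.shape[0]:
        raise ValueError("factor weight length does not match loading columns")
    if (L < 0).any():
        warnings.warn("negative rotated loadings; using absolute values")
        L = np.abs(L)
    colsum = L.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("loading column sums to zero")
    if combination == "normalized":
        B = (L / colsum) @ T
    elif combination == "literal":
        raw = L @ T
        B = raw / raw.sum()
    else:
        raise ValueError(f"unknown combination {combination!r}")
    return B


def composite_score(removals: np.ndarray, weights: np.ndarray) -> float:
    """Composite efficiency E = sum_i A_i * B_i for removal fractions A_i."""
    A = np.asarray(removals, dtype=float)
    B = np.asarray(weights, dtype=float)
    if A.shape != B.shape:
        raise ValueError("removals and weights must have equal length")
    if ((A < 0) | (A > 1)).any():
        raise ValueError("removal fractions must lie in [0, 1]")
    return float(A @ B)


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> float:
    """Mean Tucker congruence between matched columns of two loading matrices.

    Columns of ``B`` are greedily matched to columns of ``A`` by absolute
    congruence; returns the mean matched |phi|.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("loading matrices must have equal shape")
    k = A.shape[1]
    num = A.T @ B
    den = np.sqrt(np.outer((A ** 2).sum(axis=0), (B ** 2).sum(axis=0)))
    phi = np.abs(num / den)
    vals = []
    work = phi.copy()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        vals.append(phi[i, j])
        work[i, :] = -1.0
        work[:, j] = -1.0
    return float(np.mean(vals))


class CompositeEfficiencyModel:
    """Composite treatment-efficiency model over a long removal table.

    Parameters
    ----------
    removal : DataFrame
        Long removal table (system, pollutant, day, replicate, removal).
    aggregate : {'replicate_mean', 'none'}
        How observation rows for the correlation matrix are formed.
    retain : {'kaiser', int}
        Factor retention policy.
    combination : {'normalized', 'literal'}
        How indicator weights combine loadings with factor weights.

    Examples
    --------
    >>> model = CompositeEfficiencyModel(removal_df)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        removal: pd.DataFrame,
        aggregate: str = "replicate_mean",
        retain="kaiser",
        combination: str = "normalized",
    ):
        self.removal = validate_removal_table(removal)
        self.aggregate = aggregate
        self.retain = retain
        self.combination = combination

    @classmethod
    def from_tsv(cls, path, dialect: str = "long_tsv", **kwargs):
        from .tables import read_removal_table

        return cls(read_removal_table(path, dialect), **kwargs)

    def fit(self) -> "CompositeEfficiencyResults":
        corr = correlation_matrix(self.removal, self.aggregate)
        kmo_value = kmo(corr)
        if kmo_value <= 0.6:
            warnings.warn(
                f"KMO = {kmo_value:.3f} <= 0.6: sampling adequacy is marginal "
                "for factor analysis"
            )
        chi2, df, pval = bartlett(corr)
        if pval > 0.05:
            warnings.warn(
                f"Bartlett sphericity p = {pval:.3g}: correlation matrix may "
                "not differ from identity"
            )
        fm = extract_factors(corr, self.retain)
        T = factor_weights(fm)
        B = indicator_weights(fm, T, self.combination)

        wide = _observation_matrix(self.removal, "replicate_mean")
        wide = wide[corr.labels]
        scores = pd.DataFrame(
            {
                "system": wide.index.get_level_values("system"),
                "day": wide.index.get_level_values("day"),
                "E": wide.to_numpy() @ B,
            }
        ).reset_index(drop=True)
        return CompositeEfficiencyResults(
            model=self,
            corr=corr,
            kmo=kmo_value,
            bartlett_chi2=chi2,
            bartlett_df=df,
            bartlett_p=pval,
            factor_model=fm,
            factor_weights=T,
            indicator_weights=pd.Series(B, index=corr.labels, name="weight"),
            scores=scores,
        )


@dataclass
class CompositeEfficiencyResults:
    """Fitted composite-efficiency results: diagnostics, weights, scores."""

    model: CompositeEfficiencyModel
    corr: CorrelationMatrix
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    factor_model: FactorModel
    factor_weights: np.ndarray
    indicator_weights: pd.Series
    scores: pd.DataFrame

    def final_scores(self) -> pd.Series:
        """Composite score per system on the last observed day."""
        last = self.scores["day"].max()
        sub = self.scores[self.scores["day"] == last]
        return sub.set_index("system")["E"]

    def summary(self) -> str:
        fm = self.factor_model
        lines = [
            "Composite treatment-efficiency model",
            "=" * 52,
            f"observations: {self.corr.n_obs}   indicators: {len(self.corr.labels)}"
            f"   factors retained: {fm.k}",
            f"KMO sampling adequacy: {self.kmo:.3f}",
            f"Bartlett sphericity:   chi2 = {self.bartlett_chi2:.2f}, "
            f"df = {self.bartlett_df}, p = {self.bartlett_p:.3g}",
            "",
            "Variance explained",
            fm.variance_table().to_string(index=False, float_format="%.3f"),
            "",
            "Rotated loadings (varimax)",
            fm.loadings_frame().to_string(float_format="%.3f"),
            "",
            "Factor weights: "
            + ", ".join(f"{t:.4f}" for t in self.factor_weights),
            "",
            "Indicator weights",
            self.indicator_weights.to_string(float_format="%.4f"),
            "",
            "Final-day composite scores",
            self.final_scores().to_string(float_format="%.4f"),
        ]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write variance table, loadings, weights, scores and diagnostics."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fm = self.factor_model
        fm.variance_table().to_csv(out / "variance_table.tsv", sep="\t", index=False)
        fm.loadings_frame().to_csv(out / "loadings.tsv", sep="\t")
        self.indicator_weights.rename_axis("pollutant").to_frame().to_csv(
            out / "weights.tsv", sep="\t"
        )
        self.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        (out / "diagnostics.json").write_text(
            json.dumps(
                {
                    "kmo": self.kmo,
                    "bartlett_chi2": self.bartlett_chi2,
                    "bartlett_df": self.bartlett_df,
                    "bartlett_p": self.bartlett_p,
                    "n_obs": self.corr.n_obs,
                    "factors_retained": fm.k,
                    "factor_weights": list(map(float, self.factor_weights)),
                },
                indent=2,
            )
        )


def score_pipeline(removal: pd.DataFrame, **kwargs) -> CompositeEfficiencyResults:
    """Run the full scoring chain on a long removal table."""
    return CompositeEfficiencyModel(removal, **kwargs).fit()
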