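"""Three-step Baron-Kenny-style mediation of the EF -> EM effect.

The total effect of X (executive function) on Y (episodic memory) is
decomposed through a mediator M (connectivity strength) with three OLS
regressions, each with an intercept:

    (1)  Y = c  X + e1          total effect
    (2)  M = a  X + e2          X -> mediator path
    (3)  Y = c' X + b M + e3    direct effect and mediator -> Y path

Without covariates, OLS guarantees c = c' + a*b exactly.  Mediation is
classified by three conditions: c significant; a and b significant;
and either c' insignificant (full mediation) or |c'| < |c| (partial).
The mediated fraction is the indirect ratio (a*b)/c, reported only when
c is significant (it is unstable near c = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class PathEstimate:
    coef: float
    se: float
    p: float

    def to_dict(self) -> dict:
        return {"coef": self.coef, "se": self.se, "p": self.p}


@dataclass
class MediationResult:
    """Coefficients of the three regressions plus the classification."""

    a: PathEstimate
    b: PathEstimate
    c: PathEstimate
    c_prime: PathEstimate
    indirect: float
    indirect_ratio: float  # NaN when c is not significant
    sobel_z: float
    sobel_p: float
    classification: str  # none | partial | full
    n: int
    alpha: float
    covariate_adjusted: bool = False

    def to_dict(self) -> dict:
        return {
            "a": self.a.to_dict(), "b": self.b.to_dict(),
            "c": self.c.to_dict(), "c_prime": self.c_prime.to_dict(),
            "indirect": self.indirect,
            "indirect_ratio": self.indirect_ratio,
            "sobel_z": self.sobel_z, "sobel_p": self.sobel_p,
            "classification": self.classification,
            "n": self.n, "alpha": self.alpha,
            "covariate_adjusted": self.covariate_adjusted,
        }

    def report(self) -> str:
        lines = [
            f"mediation over n={self.n} subjects (alpha={self.alpha})",
            f"  total     c  = {self.c.coef:+.4f} (p={self.c.p:.4g})",
            f"  path      a  = {self.a.coef:+.4f} (p={self.a.p:.4g})",
            f"  path      b  = {self.b.coef:+.4f} (p={self.b.p:.4g})",
            f"  direct    c' = {self.c_prime.coef:+.4f} (p={self.c_prime.p:.4g})",
            f"  indirect a*b = {self.indirect:+.4f}",
        ]
        if np.isfinite(self.indirect_ratio):
            lines.append(f"  indirect ratio (a*b)/c = {self.indirect_ratio:.3f} "
                         f"({100 * self.indirect_ratio:.1f}% of the total effect)")
        else:
            lines.append("  indirect ratio undefined (total effect not significant)")
        lines.append(f"  classification: {self.classification}")
        return "\n".join(lines)


def _ols_path(y, x_cols) -> list[PathEstimate]:
    """Fit y ~ [1, x_cols]; return estimates for each non-intercept column."""
    design = sm.add_constant(np.column_stack(x_cols))
    fit = sm.OLS(y, design).fit()
    return [PathEstimate(coef=float(fit.params[i + 1]),
                         se=float(fit.bse[i + 1]),
                         p=float(fit.pvalues[i + 1]))
            for i in range(len(x_cols))]


def fit_mediation(x, m, y, alpha: float = 0.05,
                  covariates: np.ndarray | None = None) -> MediationResult:
    """Fit the three-regression mediation model.

    ``covariates`` (n, k), when given, are appended to every regression;
    the exact c = c' + a*b identity then no longer holds and the result
    is marked covariate-adjusted.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 subjects")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if not np.isfinite(v).all():
            raise ValueError(f"{name} contains non-finite values")
        if v.std() == 0 and name != "y":
            raise ValueError(f"{name} has zero variance")
    extra = []
    if covariates is not None:
        c_arr = np.asarray(covariates, dtype=float)
        if c_arr.ndim == 1:
            c_arr = c_arr[:, None]
        extra = [c_arr[:, i] for i in range(c_arr.shape[1])]

    c_est = _ols_path(y, [x] + extra)[0]
    a_est = _ols_path(m, [x] + extra)[0]
    cp_est, b_est = _ols_path(y, [x, m] + extra)[:2]

    indirect = a_est.coef * b_est.coef
    c_sig = c_est.p < alpha
    a_sig = a_est.p < alpha
    b_sig = b_est.p < alpha
    cp_sig = cp_est.p < alpha

    if c_sig and a_sig and b_sig:
        if not cp_sig:
            classification = "full"
        elif abs(cp_est.coef) < abs(c_est.coef):
            classification = "partial"
        else:
            classification = "none"
    else:
        classification = "none"

    ratio = indirect / c_est.coef if c_sig else float("nan")
    # Sobel z for the indirect path -- supplementary to the three-condition
    # classification, which itself uses only the per-path OLS t-tests
    sobel_se = np.sqrt(b_est.coef ** 2 * a_est.se ** 2
                       + a_est.coef ** 2 * b_est.se ** 2)
    sobel_z = indirect / sobel_se if sobel_se > 0 else 0.0
    sobel_p = float(2.0 * sps.norm.sf(abs(sobel_z)))

    return MediationResult(
        a=a_est, b=b_est, c=c_est, c_prime=cp_est,
        indirect=float(indirect), indirect_ratio=float(ratio),
        sobel_z=float(sobel_z), sobel_p=sobel_p,
        classification=classification, n=int(n), alpha=alpha,
        covariate_adjusted=covariates is not None,
    )


def extract_mediator(fc_maps: list[np.ndarray], cluster: np.ndarray) -> np.ndarray:
    """Per-subject mean Fisher-z connectivity over a cluster's voxels."""
    cluster = np.asarray(cluster, dtype=bool)
    if not cluster.any():
        raise ValueError("cluster is empty")
    return np.array([float(np.asarray(m)[cluster].mean()) for m in fc_maps])
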