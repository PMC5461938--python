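"""Independent normal-equations OLS oracle used to cross-check the model layer.

Deliberately implemented from first principles (matrix algebra plus the t
distribution), sharing no code with svdmarkers.models.
"""

import numpy as np
from scipy import stats


def ols_oracle(data, outcome, terms, site_col=None):
    """Fit OLS of ``outcome`` on ``terms`` (+ site dummies) by normal equations.

    Returns a dict per term with unstandardized and standardized estimates,
    p-values, 95% CIs, VIFs, plus adjusted R^2.
    """
    df = data.dropna(subset=[outcome] + list(terms))
    y = df[outcome].to_numpy(float)
    cols = list(terms)
    X_parts = [df[c].to_numpy(float) for c in cols]
    if site_col is not None:
        sites = sorted(df[site_col].unique())
        for s in sites[1:]:
            X_parts.append((df[site_col] == s).to_numpy(float))
            cols.append(f"site_{s}")
    X = np.column_stack([np.ones(len(y))] + X_parts)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ X.T @ y
    resid = y - X @ b
    dof = n - k
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    tvals = b / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    tcrit = stats.t.ppf(0.975, dof)
    sd_y = np.std(y, ddof=1)
    out = {}
    for j, c in enumerate(cols, start=1):
        x = X[:, j]
        scale = np.std(x, ddof=1) / sd_y
        # VIF: R^2 of column j on all other design columns (incl. intercept)
        others = np.delete(X, j, axis=1)
        bj = np.linalg.lstsq(others, x, rcond=None)[0]
        rj = x - others @ bj
        r2j = 1 - (rj @ rj) / np.sum((x - x.mean()) ** 2)
        out[c] = {
            "b": b[j],
            "se": se[j],
            "p": pvals[j],
            "ci": (b[j] - tcrit * se[j], b[j] + tcrit * se[j]),
            "std_beta": b[j] * scale,
            "std_ci": ((b[j] - tcrit * se[j]) * scale, (b[j] + tcrit * se[j]) * scale),
            "vif": 1.0 / (1.0 - r2j),
        }
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / tss
    out["_model"] = {
        "adj_r2": 1 - (1 - r2) * (n - 1) / dof,
        "n": n,
    }
    return out
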