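"""Putative drivers of amplification efficiency.

Two analyses mirror how efficiency heterogeneity is usually interrogated:

* a Mantel permutation test between pairwise template edit distances
  (Levenshtein) and pairwise differences in log efficiency — is sequence
  similarity predictive of similar amplification?
* a robust linear model log(lambda) ~ GC + E, where GC is the template's GC
  fraction and E its secondary-structure free energy (kcal/mol, supplied as
  an input; more negative = more stable fold).  Huber M-estimation bounds
  the influence of outlying templates.
"""

from __future__ import annotations

import edlib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_VALID_BASES = set("ACGTN")


def gc_content(seq: str) -> float:
    """GC fraction of a DNA sequence; N bases are excluded from the denominator."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    n_n = s.count("N")
    denom = len(s) - n_n
    if denom == 0:
        raise ValueError("sequence contains only N bases")
    return (s.count("G") + s.count("C")) / denom


def levenshtein(s1: str, s2: str) -> int:
    """Levenshtein edit distance (unit-cost substitutions/insertions/deletions)."""
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    return edlib.align(s1, s2, task="distance")["editDistance"]


def levenshtein_matrix(sequences: dict[str, str] | list[str]) -> np.ndarray:
    """Symmetric pairwise edit-distance matrix over a set of sequences."""
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(seqs[i], seqs[j])
    return d


def log_efficiency_distance(
    log_lambda: np.ndarray, metric: str = "abs"
) -> np.ndarray:
    """Pairwise distances between per-template log efficiencies.

    ``metric`` is 'abs' (|Δ log λ|, default) or 'sq' (squared differences).
    """
    ll = np.asarray(log_lambda, dtype=float)
    diff = ll[:, None] - ll[None, :]
    if metric == "abs":
        return np.abs(diff)
    if metric == "sq":
        return diff ** 2
    raise ValueError("metric must be 'abs' or 'sq'")


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel permutation test of correlation between two distance matrices.

    The statistic is the Pearson correlation of the upper-triangle entries;
    the null distribution is generated by jointly permuting rows and columns
    of ``d2``.  The p-value uses the (1 + exceedances) / (1 + permutations)
    convention, so it can never be exactly zero.  ``alternative`` is
    'greater' (one-sided, default) or 'two-sided'.

    Returns (r, p).
    """
    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have the same dimension")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = d1[iu]
    v2 = d2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    # centred/normalised v1 once; each permuted r is then a dot product
    z1 = (v1 - v1.mean()) / v1.std()
    z2 = (v2 - v2.mean()) / v2.std()
    m = v1.size
    r_obs = float(z1 @ z2 / m)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = d2[perm][:, perm][iu]
        z2p = (v2p - v2p.mean()) / v2p.std()
        r_p = z1 @ z2p / m
        if alternative == "greater":
            exceed += r_p >= r_obs
        else:
            exceed += abs(r_p) >= abs(r_obs)
    p = (1 + exceed) / (n_perm + 1)
    return r_obs, float(p)


def robust_lm(
    table: pd.DataFrame,
    response: str = "log_lambda",
    covariates: tuple[str, ...] = ("gc", "energy"),
    tuning: float = 1.345,
    norm: str = "huber",
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Robust linear model of log efficiency on template covariates.

    Huber M-estimation (default tuning 1.345, i.e. 95% Gaussian efficiency)
    via iteratively reweighted least squares; ``norm='bisquare'`` switches to
    Tukey's bisquare.  Requires at least four complete rows and a
    full-rank design.  Returns one row per coefficient (const first) with
    estimate, standard error, z statistic and p-value.
    """
    cols = [response, *covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    data = table[cols].dropna()
    if len(data) < 4:
        raise ValueError("need at least four complete rows")
    y = data[response].to_numpy(float)
    X = sm.add_constant(data[list(covariates)].to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear (rank-deficient) covariate design")
    if norm == "huber":
        m_norm = sm.robust.norms.HuberT(t=tuning)
    elif norm == "bisquare":
        m_norm = sm.robust.norms.TukeyBiweight()
    else:
        raise ValueError("norm must be 'huber' or 'bisquare'")
    res = sm.RLM(y, X, M=m_norm).fit(conv="coefs", tol=tol)
    names = ["const", *covariates]
    return pd.DataFrame(
        {
            "term": names,
            "coef": res.params,
            "stderr": res.bse,
            "z": res.tvalues,
            "pvalue": res.pvalues,
        }
    )
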