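"""Group statistical difference networks from per-subject weighted networks.

For every region pair, two one-tailed two-sample t-tests compare the
case and control weight samples: D+ flags edges whose mean weight is
significantly greater in cases, D- edges significantly smaller. Welch's
unequal-variance test is the default; pooled-variance Student and
Benjamini-Hochberg correction are options.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netbuild import WeightedNetwork, write_matrix_tsv

__all__ = ["DifferenceNetworkResult", "edge_ttest", "difference_networks"]


@dataclass(frozen=True)
class DifferenceNetworkResult:
    """Binary difference networks with their one-tailed p-value maps."""

    d_plus: np.ndarray
    d_minus: np.ndarray
    p_plus: np.ndarray
    p_minus: np.ndarray
    alpha: float
    correction: str | None = None

    @property
    def plus_edges(self) -> list[tuple[int, int]]:
        """Flagged D+ edges as 1-based (i, j) pairs, i < j."""
        return [(int(i) + 1, int(j) + 1) for i, j in zip(*np.triu_indices_from(self.d_plus, 1))
                if self.d_plus[i, j]]

    @property
    def minus_edges(self) -> list[tuple[int, int]]:
        return [(int(i) + 1, int(j) + 1) for i, j in zip(*np.triu_indices_from(self.d_minus, 1))
                if self.d_minus[i, j]]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_matrix_tsv(self.d_plus, out_dir / "d_plus.tsv", fmt="%d")
        write_matrix_tsv(self.d_minus, out_dir / "d_minus.tsv", fmt="%d")
        write_matrix_tsv(self.p_plus, out_dir / "p_plus.tsv")
        write_matrix_tsv(self.p_minus, out_dir / "p_minus.tsv")
        for name, edges, pmat in (
            ("d_plus_edges.tsv", self.plus_edges, self.p_plus),
            ("d_minus_edges.tsv", self.minus_edges, self.p_minus),
        ):
            lines = ["region_i\tregion_j\tp_value"]
            lines += [f"{i}\t{j}\t{pmat[i - 1, j - 1]:.6g}" for i, j in edges]
            (out_dir / name).write_text("\n".join(lines) + "\n")


def edge_ttest(a, b, tail: str = "greater", equal_var: bool = False) -> float:
    """One-tailed two-sample t-test p-value for mean(a) vs mean(b).

    ``tail="greater"`` tests mean(a) > mean(b); ``"less"`` the reverse.
    Two constant, equal samples have an undefined statistic and report
    p = 1 (no evidence of a difference).
    """
    if tail not in ("greater", "less"):
        raise ValueError(f"tail must be 'greater' or 'less', got {tail!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return 0.0 if (sign > 0) == (tail == "greater") else 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=tail)
    return float(res.pvalue)


def _pvalue_matrices(case_stack, control_stack, tail, equal_var):
    n = case_stack.shape[1]
    iu, ju = np.triu_indices(n, 1)
    a = case_stack[:, iu, ju]
    b = control_stack[:, iu, ju]
    res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var, alternative=tail)
    p = np.asarray(res.pvalue, dtype=float)
    bad = np.flatnonzero(~np.isfinite(p))
    for k in bad:
        p[k] = edge_ttest(a[:, k], b[:, k], tail=tail, equal_var=equal_var)
    mat = np.ones((n, n))
    mat[iu, ju] = p
    mat[ju, iu] = p
    return mat, p, (iu, ju)


def difference_networks(
    case_fws: list[WeightedNetwork],
    control_fws: list[WeightedNetwork],
    alpha: float = 0.05,
    equal_var: bool = False,
    correction: str | None = None,
) -> DifferenceNetworkResult:
    """Edge-wise one-tailed difference networks D+ and D-.

    ``correction=None`` thresholds raw per-edge p-values at ``alpha``;
    ``correction="bh"`` applies Benjamini-Hochberg across all edges on
    each side before thresholding.
    """
    if len(case_fws) < 2 or len(control_fws) < 2:
        raise ValueError("need at least 2 networks per group")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if correction not in (None, "bh"):
        raise ValueError(f"correction must be None or 'bh', got {correction!r}")
    sizes = {fw.region_count for fw in case_fws} | {fw.region_count for fw in control_fws}
    if len(sizes) != 1:
        raise ValueError(f"subjects have mismatched region counts: {sorted(sizes)}")
    case_stack = np.stack([fw.weights for fw in case_fws])
    control_stack = np.stack([fw.weights for fw in control_fws])
    n = sizes.pop()

    out = {}
    for key, tail in (("plus", "greater"), ("minus", "less")):
        pmat, pflat, (iu, ju) = _pvalue_matrices(case_stack, control_stack, tail, equal_var)
        if correction == "bh":
            reject, _, _, _ = multipletests(pflat, alpha=alpha, method="fdr_bh")
        else:
            reject = pflat < alpha
        d = np.zeros((n, n), dtype=np.int8)
        d[iu, ju] = reject
        d[ju, iu] = reject
        out[key] = (d, pmat)
    return DifferenceNetworkResult(
        d_plus=out["plus"][0],
        d_minus=out["minus"][0],
        p_plus=out["plus"][1],
        p_minus=out["minus"][1],
        alpha=alpha,
        correction=correction,
    )
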