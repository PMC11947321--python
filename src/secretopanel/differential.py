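"""Normalization, per-protein two-sample testing, and FDR control.

Collapsed abundances are normalized as ``log2(n + 1)`` with not-detected
treated as ``n = 0`` — the ``+1`` exists precisely to accommodate zeros, so
missingness becomes a zero signal rather than a dropped observation.  Each
protein is then compared between two sides of a contrast with a two-sided,
unpaired t-test (Welch by default; Student's pooled-variance variant by flag),
and Benjamini–Hochberg adjustment is applied within each contrast across its
tested proteins.

Degenerate inputs follow an explicit contract instead of propagating NaN:
when both sides have zero variance and equal means the result is ``t = 0,
p = 1``; when both have zero variance and unequal means the difference is
unambiguous, so ``p = 0`` with a ``degenerate`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .filtering import DetectionMatrix

REST = "rest"  # pseudo-group label for one-vs-rest contrasts


@dataclass(frozen=True)
class Contrast:
    """A named comparison between two disjoint sets of groups.

    ``side_a`` and ``side_b`` each name one group or a pooled set of groups;
    one-vs-rest contrasts pool every remaining group into ``side_b``.
    """

    name: str
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ConfigurationError(f"contrast {self.name!r}: both sides must be nonempty")
        if set(self.side_a) & set(self.side_b):
            raise ConfigurationError(f"contrast {self.name!r}: sides must be disjoint")

    @staticmethod
    def pairwise(a: str, b: str) -> "Contrast":
        return Contrast(f"{a}_vs_{b}", (a,), (b,))

    @staticmethod
    def one_vs_rest(group: str, all_groups: Iterable[str]) -> "Contrast":
        rest = tuple(g for g in all_groups if g != group)
        return Contrast(f"{group}_vs_{REST}", (group,), rest)


def log2p1_normalize(det: DetectionMatrix) -> pd.DataFrame:
    """``log2(n + 1)`` on collapsed abundances, not-detected as ``n = 0``.

    The output is a proteins × samples frame with no missing entries.
    """
    values = det.values.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValidationError("collapsed abundances must be nonnegative")
    return pd.DataFrame(
        np.log2(np.nan_to_num(values, nan=0.0) + 1.0),
        index=det.values.index,
        columns=det.values.columns,
    )


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, flavor: str = "welch"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided unpaired t-test.  Returns (t, p, degenerate).

    ``a`` and ``b`` are 2-D (features × observations).  Zero-variance rows
    follow the degenerate contract documented at module level.
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("each side needs ≥ 2 observations")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if flavor == "welch":
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    elif flavor == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full_like(se2, float(na + nb - 2))
    else:
        raise ConfigurationError(f"unknown t-test flavor {flavor!r}")
    diff = ma - mb
    degenerate = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    equal_degenerate = degenerate & (diff == 0.0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(degenerate, np.where(diff == 0.0, 1.0, 0.0), p)
    return t, p, degenerate & ~equal_degenerate


def protein_t_test(
    side_a: Sequence[float], side_b: Sequence[float], flavor: str = "welch"
) -> tuple[float, float, float, bool]:
    """Test one protein; returns (log2FC, t, p, degenerate flag).

    ``log2FC`` is the mean of ``side_a`` minus the mean of ``side_b`` on the
    already-normalized ``log2(n + 1)`` scale.
    """
    a = np.asarray(side_a, dtype=float)[None, :]
    b = np.asarray(side_b, dtype=float)[None, :]
    t, p, degenerate = _two_sample_t(a, b, flavor=flavor)
    return float(a.mean() - b.mean()), float(t[0]), float(p[0]), bool(degenerate[0])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    Sort ascending, take ``q(i) = min_{j ≥ i} p(j)·m/j`` capped at 1, and
    return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def run_contrasts(
    det: DetectionMatrix,
    contrasts: Sequence[Contrast],
    restrict_to: Iterable[str] | None = None,
    flavor: str = "welch",
) -> dict[str, pd.DataFrame]:
    """Run every contrast over the (optionally restricted) protein set.

    Each result table carries, per protein: ``log2fc``, ``t``, ``p``, ``fdr``
    (BH within the contrast), per-side identification coverage and sample
    counts, and a ``degenerate`` zero-variance flag.  Proteins untestable in
    a contrast (a side with fewer than two samples) are kept in the table
    with NaN statistics and excluded from the FDR universe.
    """
    groups = set(det.groups)
    normalized = log2p1_normalize(det)
    if restrict_to is not None:
        wanted = pd.Index(restrict_to)
        missing = wanted.difference(normalized.index)
        if len(missing):
            raise ValidationError(f"unknown proteins in restrict_to: {list(missing)[:5]}")
        normalized = normalized.loc[normalized.index.intersection(wanted)]
    detected = det.detected.loc[normalized.index]

    results: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        unknown = (set(contrast.side_a) | set(contrast.side_b)) - groups
        if unknown:
            raise ConfigurationError(
                f"contrast {contrast.name!r} references unknown group(s) {sorted(unknown)}"
            )
        cols_a = det.sample_groups.index[det.sample_groups.isin(contrast.side_a)]
        cols_b = det.sample_groups.index[det.sample_groups.isin(contrast.side_b)]
        a = normalized[list(cols_a)].to_numpy()
        b = normalized[list(cols_b)].to_numpy()
        table = pd.DataFrame(index=normalized.index)
        if a.shape[1] < 2 or b.shape[1] < 2:
            # whole contrast untestable: keep shape, flag all rows
            table[["log2fc", "t", "p", "fdr"]] = np.nan
            table["degenerate"] = False
        else:
            t, p, degenerate = _two_sample_t(a, b, flavor=flavor)
            table["log2fc"] = a.mean(axis=1) - b.mean(axis=1)
            table["t"] = t
            table["p"] = p
            table["fdr"] = bh_adjust(p) if len(p) else p
            table["degenerate"] = degenerate
        table["coverage_a"] = detected[list(cols_a)].mean(axis=1)
        table["coverage_b"] = detected[list(cols_b)].mean(axis=1)
        table["n_a"] = len(cols_a)
        table["n_b"] = len(cols_b)
        results[contrast.name] = table
    return results


def default_contrasts(groups: Sequence[str]) -> list[Contrast]:
    """All pairwise contrasts (later group vs earlier) plus one-vs-rest each.

    With groups ordered (control, treated1, treated2) this yields the
    treated-vs-control orientation for the pairwise tables.
    """
    out: list[Contrast] = []
    for j in range(len(groups)):
        for i in range(j):
            out.append(Contrast.pairwise(groups[j], groups[i]))
    for g in groups:
        out.append(Contrast.one_vs_rest(g, groups))
    return out
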