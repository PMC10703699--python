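"""Single-cell gRNA assignment and screen-concordance scoring.

In the single-cell follow-up, gRNA capture yields a cell x guide UMI
matrix.  Guides are assigned to cells when their UMI count strictly
exceeds a threshold (default 4); cells failing transcriptome QC
(detected genes, mitochondrial and ribosomal fractions) are dropped
first.  Per-guide marker responses against the NT-only cell pool are then
compared with the sorted-screen hits to produce true-positive /
true-negative concordance rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import NON_TARGETING

__all__ = [
    "qc_filter_cells",
    "assign_guides",
    "AssignmentSummary",
    "marker_response_test",
    "concordance_rates",
    "ConcordanceReport",
    "read_mtx_triplets",
]


def qc_filter_cells(
    stats_df: pd.DataFrame,
    min_genes: int = 200,
    max_mito: float = 20.0,
    min_ribo: float = 5.0,
) -> pd.Index:
    """Keep cells passing transcriptome QC.

    Cells with fewer than ``min_genes`` detected genes, more than
    ``max_mito`` percent mitochondrial reads, or less than ``min_ribo``
    percent ribosomal reads are discarded; boundary values are kept (the
    discard rules are strict inequalities).
    """
    keep = (
        (stats_df["n_genes_detected"] >= min_genes)
        & (stats_df["pct_mito"] <= max_mito)
        & (stats_df["pct_ribo"] >= min_ribo)
    )
    return stats_df.index[keep]


@dataclass
class AssignmentSummary:
    n_unassigned: int
    n_singlet: int
    n_multiplet: int


def assign_guides(
    umi: pd.DataFrame, threshold: int = 4
) -> tuple[dict[str, set[str]], AssignmentSummary]:
    """Assign guides to cells by UMI count strictly greater than
    ``threshold``.

    Returns a cell -> guide-id-set mapping (every cell present, possibly
    empty) plus singlet/multiplet/unassigned tallies.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    M = umi.to_numpy()
    hits = M > threshold
    guide_ids = np.asarray(umi.columns)
    assignments = {
        cell: set(guide_ids[row]) for cell, row in zip(umi.index, hits)
    }
    n_per_cell = hits.sum(axis=1)
    summary = AssignmentSummary(
        n_unassigned=int((n_per_cell == 0).sum()),
        n_singlet=int((n_per_cell == 1).sum()),
        n_multiplet=int((n_per_cell > 1).sum()),
    )
    return assignments, summary


def marker_response_test(
    expression: pd.Series,
    assignments: dict[str, set[str]],
    nt_guide_ids,
    alpha: float = 0.05,
    min_cells: int = 5,
    exclude_multiplets: bool = True,
    include_nt_guides: bool = False,
    test=None,
) -> pd.DataFrame:
    """Per-guide marker response against the NT-only cell pool.

    For every targeting guide with at least ``min_cells`` assigned cells, a
    two-sided rank-sum test compares its cells' marker expression with
    cells carrying only NT guides; Bonferroni correction runs across the
    tested guides and the direction is the sign of the median shift.
    ``test(x, y) -> p`` is pluggable (defaults to Mann-Whitney U).
    Multiplet cells are excluded from guide groups by default.  With
    ``include_nt_guides`` each NT guide is itself tested — its cells
    against the NT-only cells *not* carrying it — which measures the
    procedure's false-positive (1 - TN) rate.
    """
    nt_set = set(nt_guide_ids)
    nt_cells = [
        c for c, g in assignments.items() if g and g <= nt_set
    ]
    if not nt_cells:
        raise ValueError("no NT-only cells; cannot form the control pool")
    nt_expr = expression.loc[nt_cells].to_numpy()

    by_guide: dict[str, list[str]] = {}
    for cell, gset in assignments.items():
        targeting = gset - nt_set
        if not targeting:
            continue
        if exclude_multiplets and len(gset) > 1:
            continue
        for g in targeting:
            by_guide.setdefault(g, []).append(cell)

    if test is None:
        def test(x, y):
            return stats.mannwhitneyu(x, y, alternative="two-sided").pvalue

    rows = []
    for guide, cells in sorted(by_guide.items()):
        if len(cells) < min_cells:
            rows.append(dict(guide_id=guide, n_cells=len(cells),
                             direction=0, pvalue=np.nan, tested=False))
            continue
        x = expression.loc[cells].to_numpy()
        p = float(test(x, nt_expr))
        direction = int(np.sign(np.median(x) - np.median(nt_expr)))
        rows.append(dict(guide_id=guide, n_cells=len(cells),
                         direction=direction, pvalue=p, tested=True))
    if include_nt_guides:
        for guide in sorted(nt_set):
            cells = [
                c for c in nt_cells
                if guide in assignments[c]
                and not (exclude_multiplets and len(assignments[c]) > 1)
            ]
            rest = [c for c in nt_cells if guide not in assignments[c]]
            if len(cells) < min_cells or not rest:
                rows.append(dict(guide_id=guide, n_cells=len(cells),
                                 direction=0, pvalue=np.nan, tested=False))
                continue
            x = expression.loc[cells].to_numpy()
            y = expression.loc[rest].to_numpy()
            p = float(test(x, y))
            direction = int(np.sign(np.median(x) - np.median(y)))
            rows.append(dict(guide_id=guide, n_cells=len(cells),
                             direction=direction, pvalue=p, tested=True))
    out = pd.DataFrame(
        rows, columns=["guide_id", "n_cells", "direction", "pvalue", "tested"]
    ).set_index("guide_id")
    n_tested = int(out["tested"].sum())
    out["p_bonf"] = np.minimum(out["pvalue"] * max(n_tested, 1), 1.0)
    out["significant"] = out["p_bonf"] < alpha
    return out


@dataclass
class ConcordanceReport:
    """TP/TN concordance of single-cell responses with screen hits."""

    tp_rate: float
    tn_rate: float
    n_hit_tested: int
    n_nt_tested: int
    per_guide: pd.DataFrame
    tp_rate_nondirectional: float = np.nan


def concordance_rates(
    screen_hits: dict[str, int],
    responses: pd.DataFrame,
    nt_guide_ids,
) -> ConcordanceReport:
    """Score single-cell marker responses against sorted-screen hits.

    ``screen_hits`` maps hit guide ids to the screen's expected direction
    (+1 marker-up, -1 marker-down).  TP rate: fraction of tested hit
    guides significant in the concordant direction (a non-directional
    variant is also reported).  TN rate: fraction of tested NT guides that
    are non-significant.  Hit and NT sets must be disjoint.
    """
    nt_set = set(nt_guide_ids)
    if nt_set & set(screen_hits):
        raise ValueError("hit and NT guide sets overlap")

    hit_rows = responses[responses.index.isin(screen_hits) & responses["tested"]]
    calls = []
    n_tp = n_tp_any = 0
    for guide, row in hit_rows.iterrows():
        concordant = bool(row["significant"]) and (
            int(row["direction"]) == int(np.sign(screen_hits[guide]))
        )
        n_tp += concordant
        n_tp_any += bool(row["significant"])
        calls.append(dict(guide_id=guide, kind="hit",
                          significant=bool(row["significant"]),
                          concordant=concordant))
    # NT guides are not tested against the NT pool; an NT "call" is any
    # response table entry, so by construction the tested NT set comes from
    # a responses table built with NT guides treated as targeting.
    nt_rows = responses[responses.index.isin(nt_set) & responses["tested"]]
    n_tn = 0
    for guide, row in nt_rows.iterrows():
        quiet = not bool(row["significant"])
        n_tn += quiet
        calls.append(dict(guide_id=guide, kind="nt",
                          significant=bool(row["significant"]),
                          concordant=quiet))
    per_guide = pd.DataFrame(
        calls, columns=["guide_id", "kind", "significant", "concordant"]
    )
    n_hit = len(hit_rows)
    n_nt = len(nt_rows)
    return ConcordanceReport(
        tp_rate=n_tp / n_hit if n_hit else np.nan,
        tn_rate=n_tn / n_nt if n_nt else np.nan,
        n_hit_tested=n_hit,
        n_nt_tested=n_nt,
        per_guide=per_guide,
        tp_rate_nondirectional=n_tp_any / n_hit if n_hit else np.nan,
    )


def read_mtx_triplets(mtx_path, barcodes_path, features_path) -> pd.DataFrame:
    """Read a cell x guide UMI matrix from MatrixMarket triplets plus
    barcode/feature text files (features as rows, cells as columns, as
    emitted by CellRanger-style pipelines)."""
    from scipy.io import mmread

    M = mmread(str(mtx_path)).tocsr()
    barcodes = [l.strip() for l in open(barcodes_path) if l.strip()]
    features = [l.strip().split("\t")[0] for l in open(features_path) if l.strip()]
    dense = np.asarray(M.todense())
    if dense.shape == (len(features), len(barcodes)):
        dense = dense.T
    return pd.DataFrame(dense, index=barcodes, columns=features)
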