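"""SaCas9 gRNA library design.

Pooled sort-bin screens start from a guide library tiling promoter/TSS
windows with spacers placed immediately 5' of an SaCas9 protospacer-adjacent
motif (PAM).  dSaCas9 effectors recognise the strict PAM 5'-NNGRRT-3' or the
relaxed variant 5'-NNGRRN-3'.  This module scans design windows for PAM
sites on both strands, removes promiscuous spacers by an ungapped
Hamming-distance off-target filter against a user-supplied background,
generates composition-matched non-targeting (NT) control spacers, and audits
the assembled library.

Coordinates are 0-based half-open on the forward strand internally and cover
the spacer only (PAM excluded).  Exported tables are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

NON_TARGETING = "NON_TARGETING"

#: IUPAC nucleotide codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _pam_sets(pam_pattern: str) -> tuple[frozenset, ...]:
    try:
        return tuple(frozenset(IUPAC[c]) for c in pam_pattern.upper())
    except KeyError as exc:  # pragma: no cover - config error path
        raise ValueError(f"invalid IUPAC code in PAM pattern: {exc}") from exc


def _matches_pam(seq: str, start: int, pam_sets: tuple[frozenset, ...]) -> bool:
    for off, allowed in enumerate(pam_sets):
        if seq[start + off] not in allowed:
            return False
    return True


@dataclass
class GuideRecord:
    """One spacer, targeting or non-targeting.

    ``start``/``end`` delimit the spacer only (0-based half-open, forward
    strand); the PAM sits immediately 3' of the spacer on the protospacer
    strand.  ``cut_window_offset`` is the signed distance from the spacer
    5' end to the design anchor (typically the TSS).
    """

    guide_id: str
    spacer: str
    pam: str | None = None
    target_gene: str = NON_TARGETING
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    cut_window_offset: int | None = None

    @property
    def is_nt(self) -> bool:
        return self.target_gene == NON_TARGETING


@dataclass
class LibraryAudit:
    """Composition summary of a guide library."""

    n_total: int
    n_nt: int
    n_targeting: int
    n_genes_targeted: int
    guides_per_gene: dict[str, int]
    mean_guides_per_gene: float
    min_guides_per_gene: int
    untargeted_genes: tuple[str, ...] = ()


class GuideLibrary:
    """An ordered gRNA library: targeting records plus NT controls.

    Duplicate spacers among targeting records are dropped (first occurrence
    kept) with a warning; duplicate guide ids are an error.
    """

    TSV_HEADER = (
        "# sortscreen guide library; start/end are 1-based inclusive, "
        "spacer only (PAM excluded); NT rows blank in positional columns"
    )

    def __init__(
        self,
        records: Iterable[GuideRecord],
        pam_pattern: str = "NNGRRT",
        spacer_length: int = 21,
        design_windows: Mapping[str, tuple[int, int]] | None = None,
        untargeted_genes: Sequence[str] = (),
    ):
        records = list(records)
        seen_spacers: dict[str, str] = {}
        seen_ids: set[str] = set()
        kept: list[GuideRecord] = []
        for rec in records:
            if rec.guide_id in seen_ids:
                raise ValueError(f"duplicate guide_id {rec.guide_id!r}")
            seen_ids.add(rec.guide_id)
            if not rec.is_nt and rec.spacer in seen_spacers:
                warnings.warn(
                    f"duplicate spacer {rec.spacer} in {rec.guide_id} "
                    f"(kept first occurrence {seen_spacers[rec.spacer]})",
                    stacklevel=2,
                )
                continue
            if not rec.is_nt:
                seen_spacers[rec.spacer] = rec.guide_id
            kept.append(rec)
        self.records = kept
        self.pam_pattern = pam_pattern
        self.spacer_length = spacer_length
        self.design_windows = dict(design_windows or {})
        self.untargeted_genes = tuple(untargeted_genes)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def targeting(self) -> list[GuideRecord]:
        return [r for r in self.records if not r.is_nt]

    @property
    def nt(self) -> list[GuideRecord]:
        return [r for r in self.records if r.is_nt]

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def spacers(self) -> list[str]:
        return [r.spacer for r in self.records]

    def gene_map(self) -> pd.Series:
        """guide_id -> target_gene (NT guides map to NON_TARGETING)."""
        return pd.Series(
            {r.guide_id: r.target_gene for r in self.records}, name="target_gene"
        )

    def guides_per_gene(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.targeting:
            out[r.target_gene] = out.get(r.target_gene, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "guide_id": r.guide_id,
                    "spacer": r.spacer,
                    "pam": r.pam or "",
                    "target_gene": r.target_gene,
                    "chrom": r.chrom or "",
                    # exported coordinates: 1-based inclusive
                    "start": "" if r.start is None else r.start + 1,
                    "end": "" if r.end is None else r.end,
                    "strand": r.strand or "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "guide_id", "spacer", "pam", "target_gene",
                "chrom", "start", "end", "strand",
            ],
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.TSV_HEADER + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, pam_pattern: str = "NNGRRT") -> "GuideLibrary":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        records = []
        for _, row in df.iterrows():
            nt = row["target_gene"] == NON_TARGETING
            records.append(
                GuideRecord(
                    guide_id=row["guide_id"],
                    spacer=row["spacer"],
                    pam=row["pam"] or None,
                    target_gene=row["target_gene"],
                    chrom=row["chrom"] or None,
                    start=None if nt or row["start"] == "" else int(row["start"]) - 1,
                    end=None if nt or row["end"] == "" else int(row["end"]),
                    strand=row["strand"] or None,
                )
            )
        spacer_len = len(records[0].spacer) if records else 21
        return cls(records, pam_pattern=pam_pattern, spacer_length=spacer_len)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def scan_candidate_guides(
    sequence: str,
    window: tuple[int, int],
    pam_pattern: str = "NNGRRT",
    spacer_length: int = 21,
    anchor: int = 0,
    gene: str | None = None,
    chrom: str | None = None,
) -> list[GuideRecord]:
    """Enumerate every PAM-adjacent spacer inside a design window.

    ``window`` is ``(start_offset, end_offset)`` relative to ``anchor``
    (half-open, in bp); a candidate is emitted wherever a ``spacer_length``
    spacer lies fully inside the window and sits immediately 5' of a PAM
    matching ``pam_pattern`` on either strand.  Spacers are reported 5'->3'
    on the protospacer strand; coordinates are forward-strand 0-based
    half-open over the spacer only.  Positions containing non-ACGT
    characters yield no candidates.
    """
    if len(pam_pattern) != 6:
        raise ValueError("PAM pattern must be 6 nt")
    seq = sequence.upper()
    n = len(seq)
    w0, w1 = anchor + window[0], anchor + window[1]
    if w0 < 0 or w1 > n:
        raise ValueError(
            f"window [{window[0]}, {window[1]}) around anchor {anchor} spans "
            f"[{w0}, {w1}) but sequence has length {n}"
        )
    pam_sets = _pam_sets(pam_pattern)
    plen = len(pam_pattern)
    acgt = frozenset("ACGT")
    out: list[GuideRecord] = []

    def clean(s: str) -> bool:
        return all(c in acgt for c in s)

    # forward strand: spacer [i, i+L), PAM [i+L, i+L+6)
    for i in range(w0, w1 - spacer_length + 1):
        j = i + spacer_length
        if j + plen > n:
            break
        spacer, pam = seq[i:j], seq[j : j + plen]
        if clean(spacer) and clean(pam) and _matches_pam(seq, j, pam_sets):
            out.append(
                GuideRecord(
                    guide_id=f"{gene or 'seq'}_{i}_+",
                    spacer=spacer,
                    pam=pam,
                    target_gene=gene or "target",
                    chrom=chrom,
                    start=i,
                    end=j,
                    strand="+",
                    cut_window_offset=i - anchor,
                )
            )
    # reverse strand: protospacer on the reverse complement; forward-strand
    # spacer interval [i, i+L) with the PAM complement at [i-6, i)
    rc = revcomp(seq)
    for jr in range(0, n - spacer_length - plen + 1):
        i = n - jr - spacer_length  # forward start of spacer
        if i < w0 or i + spacer_length > w1:
            continue
        spacer, pam = rc[jr : jr + spacer_length], rc[jr + spacer_length : jr + spacer_length + plen]
        if clean(spacer) and clean(pam) and _matches_pam(rc, jr + spacer_length, pam_sets):
            out.append(
                GuideRecord(
                    guide_id=f"{gene or 'seq'}_{i}_-",
                    spacer=spacer,
                    pam=pam,
                    target_gene=gene or "target",
                    chrom=chrom,
                    start=i,
                    end=i + spacer_length,
                    strand="-",
                    cut_window_offset=(i + spacer_length) - anchor,
                )
            )
    out.sort(key=lambda r: (r.start, r.strand))
    return out


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(spacers: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(spacers).encode(), dtype=np.uint8)
    return arr.reshape(len(spacers), -1)


def pam_adjacent_windows(
    background: Iterable[str], pam_pattern: str, spacer_length: int
) -> list[str]:
    """All spacer-length windows immediately 5' of a PAM match, both strands,
    across every background sequence."""
    pam_sets = _pam_sets(pam_pattern)
    plen = len(pam_pattern)
    sites: list[str] = []
    for bg in background:
        for seq in (bg.upper(), revcomp(bg.upper())):
            n = len(seq)
            for i in range(spacer_length, n - plen + 1):
                if _matches_pam(seq, i, pam_sets):
                    sites.append(seq[i - spacer_length : i])
    return sites


def filter_off_target(
    candidates: Sequence[GuideRecord],
    background: Sequence[str],
    max_mismatch_excl: int = 4,
    pam_pattern: str = "NNGRRT",
) -> list[GuideRecord]:
    """Drop candidates with PAM-adjacent background matches below the
    mismatch threshold.

    A candidate is kept iff, over every PAM-adjacent spacer-length window in
    the background (both strands, ungapped), the number of sites with
    Hamming distance < ``max_mismatch_excl`` — excluding one perfect
    self-match at the design locus — is zero.  The background must include
    the design locus itself.
    """
    if not background or all(len(b) == 0 for b in background):
        raise ValueError("empty background: cannot assess off-target specificity")
    if not candidates:
        return []
    L = len(candidates[0].spacer)
    sites = pam_adjacent_windows(background, pam_pattern, L)
    sites = [s for s in sites if set(s) <= set("ACGT")]
    if not sites:
        return list(candidates)
    bg = _encode(sites)
    kept: list[GuideRecord] = []
    for rec in candidates:
        cand = _encode([rec.spacer])[0]
        dists = (bg != cand).sum(axis=1)
        n_close = int((dists < max_mismatch_excl).sum())
        n_exact = int((dists == 0).sum())
        if n_close - min(n_exact, 1) == 0:
            kept.append(rec)
    return kept


def generate_nt_guides(
    targeting_spacers: Sequence[str],
    n: int,
    background: Sequence[str],
    seed: int,
    pam_pattern: str = "NNGRRT",
    max_mismatch_excl: int = 4,
    max_draws: int | None = None,
    existing_spacers: Iterable[str] = (),
    id_prefix: str = "NT",
) -> list[GuideRecord]:
    """Draw composition-matched non-targeting control spacers.

    Spacers are sampled position-independently from the pooled
    mononucleotide frequencies of the targeting spacers and rejected when
    they duplicate any known spacer or land within ``max_mismatch_excl``
    mismatches of any PAM-adjacent background window (so NT controls have no
    near-match anywhere, including no perfect match).  Deterministic under
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not targeting_spacers:
        raise ValueError("targeting_spacers must be non-empty")
    L = len(targeting_spacers[0])
    pooled = "".join(targeting_spacers)
    counts = np.array([pooled.count(b) for b in "ACGT"], dtype=float)
    freqs = counts / counts.sum()
    sites = pam_adjacent_windows(background, pam_pattern, L)
    sites = [s for s in sites if set(s) <= set("ACGT")]
    bg = _encode(sites) if sites else None
    taken = set(targeting_spacers) | set(existing_spacers)
    rng = np.random.default_rng(seed)
    if max_draws is None:
        max_draws = 200 * n + 1000
    out: list[GuideRecord] = []
    bases = np.array(list("ACGT"))
    draws = 0
    while len(out) < n:
        if draws >= max_draws:
            raise RuntimeError(
                f"could not generate {n} NT spacers within {draws} draws "
                f"({len(out)} accepted); background too constraining"
            )
        draws += 1
        spacer = "".join(rng.choice(bases, size=L, p=freqs))
        if spacer in taken:
            continue
        if bg is not None:
            dists = (bg != _encode([spacer])[0]).sum(axis=1)
            if (dists < max_mismatch_excl).any():
                continue
        taken.add(spacer)
        out.append(
            GuideRecord(
                guide_id=f"{id_prefix}_{len(out) + 1:04d}",
                spacer=spacer,
                target_gene=NON_TARGETING,
            )
        )
    return out


def design_tiling_library(
    tss_table: Mapping[str, tuple[str, int]] | Sequence[tuple[str, str, int]],
    window: tuple[int, int] = (-500, 500),
    pam_pattern: str = "NNGRRT",
    spacer_length: int = 21,
    background: Sequence[str] | None = None,
    n_nt: int = 120,
    seed: int = 0,
    max_mismatch_excl: int = 4,
) -> GuideLibrary:
    """Design a TSS-tiling library: scan each gene's window, filter
    off-targets against the background, then append composition-matched NT
    controls.  Genes whose window yields no surviving guide are recorded in
    ``library.untargeted_genes`` rather than silently dropped.
    """
    if isinstance(tss_table, Mapping):
        entries = [(g, s, a) for g, (s, a) in tss_table.items()]
    else:
        entries = list(tss_table)
    names = [g for g, _, _ in entries]
    if len(set(names)) != len(names):
        dupes = sorted({g for g in names if names.count(g) > 1})
        raise ValueError(f"duplicate gene names in design table: {dupes}")
    if not entries:
        raise ValueError("empty design table")
    if background is None:
        background = [s for _, s, _ in entries]

    records: list[GuideRecord] = []
    untargeted: list[str] = []
    attrition: dict[str, dict[str, int]] = {}
    for gene, seq, anchor in entries:
        cands = scan_candidate_guides(
            seq, window, pam_pattern, spacer_length, anchor=anchor, gene=gene
        )
        kept = filter_off_target(
            cands, background, max_mismatch_excl=max_mismatch_excl,
            pam_pattern=pam_pattern,
        )
        attrition[gene] = {"candidates": len(cands), "kept": len(kept)}
        if not kept:
            untargeted.append(gene)
        records.extend(kept)

    nt = generate_nt_guides(
        [r.spacer for r in records] or ["A" * spacer_length],
        n_nt,
        background,
        seed=seed,
        pam_pattern=pam_pattern,
        max_mismatch_excl=max_mismatch_excl,
    )
    lib = GuideLibrary(
        records + nt,
        pam_pattern=pam_pattern,
        spacer_length=spacer_length,
        design_windows={g: window for g, _, _ in entries},
        untargeted_genes=untargeted,
    )
    lib.attrition = attrition
    return lib


def validate_library(library: GuideLibrary) -> LibraryAudit:
    """Audit library composition (totals, NT count, guides per gene)."""
    per_gene = library.guides_per_gene()
    n_nt = len(library.nt)
    n_targeting = len(library.targeting)
    n_genes = len(per_gene)
    return LibraryAudit(
        n_total=n_nt + n_targeting,
        n_nt=n_nt,
        n_targeting=n_targeting,
        n_genes_targeted=n_genes,
        guides_per_gene=per_gene,
        mean_guides_per_gene=(n_targeting / n_genes) if n_genes else 0.0,
        min_guides_per_gene=min(per_gene.values()) if per_gene else 0,
        untargeted_genes=library.untargeted_genes,
    )
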