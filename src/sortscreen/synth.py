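"""Synthetic sorted-bin screen data with known ground truth.

The generator emulates the statistical structure the analysis assumes.
Each cell carries one guide; its marker level is Normal(delta_g, 1) where
delta_g is the guide's true marker shift in s.d. units (0 for NT guides
and unperturbed genes).  Cells are sorted into the lower and upper
``f``-tails of the *null* marker distribution (perturbed cells are assumed
a small minority of the pool), so a guide's capture probabilities are

    p_low  = Phi(Phi^-1(f) - delta)
    p_high = 1 - Phi(Phi^-1(1 - f) - delta)

and its expected log2 fold change HIGH vs LOW is log2(p_high / p_low).
Per donor, guide abundances are log-normal; sequencing counts are negative
binomial (variance mu + phi mu^2) around depth-scaled expected
abundances.  The same module simulates error-bearing FASTQ reads (the
inverse of the spacer counter) and cell x guide UMI matrices with ambient
background, plus miscalibrated NT p-value draws for stressing the
empirical calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library import NON_TARGETING, GuideLibrary, GuideRecord
from .quantify import AUTO, CountMatrix, ReadExtractionSpec

__all__ = [
    "ScreenSimConfig",
    "simulate_sort_screen",
    "expected_log2fc",
    "simulate_fastq",
    "simulate_cell_guide_umis",
    "simulate_nt_pvalues",
    "synthetic_library",
]


@dataclass
class ScreenSimConfig:
    """Study conditions for a simulated sorted-bin screen.

    Defaults mirror the screens the analysis targets: 200 genes with 8
    guides each plus 120 NT controls, 3 donors, 10% sort tails, 300x
    sequencing depth per sample, NB dispersion 0.05 and a log-normal guide
    abundance spread of 0.3 (log s.d.).  ``effects`` maps gene names to
    their true marker shift delta (s.d. units); unlisted genes are null.
    """

    n_genes: int = 200
    guides_per_gene: int = 8
    n_nt: int = 120
    n_donors: int = 3
    tail_fraction: float = 0.10
    depth: float = 300.0
    dispersion: float = 0.05
    abundance_sigma: float = 0.3
    effects: dict[str, float] = field(default_factory=dict)
    arm: str = "CRISPRi"
    marker: str = "CCR7"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.tail_fraction <= 0.5):
            raise ValueError("tail_fraction must lie in (0, 0.5]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1:03d}" for i in range(self.n_genes)]


def expected_log2fc(delta, f: float):
    """Expected log2(HIGH/LOW) capture ratio for marker shift ``delta``
    and tail fraction ``f``; antisymmetric in delta."""
    if not (0.0 < f <= 0.5):
        raise ValueError("f must lie in (0, 0.5]")
    delta = np.asarray(delta, dtype=float)
    p_low = stats.norm.cdf(stats.norm.ppf(f) - delta)
    p_high = stats.norm.sf(stats.norm.ppf(1.0 - f) - delta)
    out = np.log2(p_high / p_low)
    return float(out) if out.ndim == 0 else out


def synthetic_library(config: ScreenSimConfig) -> GuideLibrary:
    """A label-only guide library matching the simulated screen (random
    ACGT spacers, no genomic coordinates)."""
    rng = np.random.default_rng(config.seed + 1)
    bases = np.array(list("ACGT"))
    records = []
    seen: set[str] = set()

    def draw_spacer() -> str:
        while True:
            s = "".join(rng.choice(bases, size=21))
            if s not in seen:
                seen.add(s)
                return s

    for gene in config.gene_names():
        for j in range(config.guides_per_gene):
            records.append(GuideRecord(
                guide_id=f"{gene}_g{j + 1}", spacer=draw_spacer(),
                pam="AAGAGT", target_gene=gene,
            ))
    for j in range(config.n_nt):
        records.append(GuideRecord(
            guide_id=f"NT_g{j + 1:03d}", spacer=draw_spacer(),
            target_gene=NON_TARGETING,
        ))
    return GuideLibrary(records, pam_pattern="NNGRRT", spacer_length=21)


def simulate_sort_screen(
    config: ScreenSimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate paired LOW/HIGH sort-bin guide counts with known truth.

    Returns ``(count_matrix, sample_sheet, truth)``; ``truth`` has one row
    per guide with its gene, delta, capture probabilities and expected
    log2 fold change.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    f = config.tail_fraction
    genes = config.gene_names()
    guide_ids, guide_genes, deltas = [], [], []
    for gene in genes:
        d = float(config.effects.get(gene, 0.0))
        for j in range(config.guides_per_gene):
            guide_ids.append(f"{gene}_g{j + 1}")
            guide_genes.append(gene)
            deltas.append(d)
    for j in range(config.n_nt):
        guide_ids.append(f"NT_g{j + 1:03d}")
        guide_genes.append(NON_TARGETING)
        deltas.append(0.0)
    deltas = np.asarray(deltas)
    G = len(guide_ids)

    p_low = stats.norm.cdf(stats.norm.ppf(f) - deltas)
    p_high = stats.norm.sf(stats.norm.ppf(1.0 - f) - deltas)

    samples, columns = [], {}
    for d in range(config.n_donors):
        donor = f"donor{d + 1}"
        abundance = np.exp(rng.normal(0.0, config.abundance_sigma, size=G))
        for bin_name, p_bin in (("LOW", p_low), ("HIGH", p_high)):
            expected = abundance * p_bin
            mu = expected * (config.depth * G / expected.sum())
            if config.dispersion > 0:
                r = 1.0 / config.dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = rng.poisson(mu)
            sid = f"{donor}_{bin_name}"
            columns[sid] = counts
            samples.append(dict(
                sample_id=sid, donor=donor, bin=bin_name,
                arm=config.arm, marker=config.marker, fastq_path="",
            ))
    sample_sheet = pd.DataFrame(samples)
    counts = pd.DataFrame(columns, index=pd.Index(guide_ids, name="guide_id"))
    truth = pd.DataFrame(
        {
            "gene": guide_genes,
            "delta": deltas,
            "p_low": p_low,
            "p_high": p_high,
            "expected_log2fc": np.log2(p_high / p_low),
        },
        index=counts.index,
    )
    cm = CountMatrix(counts=counts, samples=sample_sheet)
    return cm, sample_sheet, truth


def simulate_fastq(
    counts: dict[str, int],
    library: GuideLibrary,
    spec: ReadExtractionSpec | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    out=None,
    read_length: int | None = None,
):
    """Emit FASTQ reads embedding each guide's spacer per the extraction
    spec, with per-base substitution errors at ``error_rate``.

    Exactly ``counts[g]`` reads are emitted per guide.  ``out`` may be a
    path or text handle; when omitted the FASTQ text is returned as a
    string.  Deterministic under ``seed``.
    """
    spec = spec or ReadExtractionSpec()
    rng = np.random.default_rng(seed)
    spacer_of = {rec.guide_id: rec.spacer for rec in library}
    bases = np.array(list("ACGT"))
    L = library.spacer_length

    if spec.spacer_offset == AUTO:
        prefix_len = len(spec.anchor_prefix)
    else:
        prefix_len = int(spec.spacer_offset)
    if read_length is None:
        read_length = prefix_len + L + max(len(spec.anchor_suffix), 4)

    lines: list[str] = []
    ridx = 0
    for guide_id in sorted(counts):
        n = int(counts[guide_id])
        if n < 0:
            raise ValueError(f"negative read count for {guide_id}")
        spacer = spacer_of[guide_id]
        for _ in range(n):
            ridx += 1
            if spec.spacer_offset == AUTO:
                head = spec.anchor_prefix
            else:
                head = "".join(rng.choice(bases, size=prefix_len))
            tail_len = read_length - len(head) - L
            tail = (spec.anchor_suffix + "".join(
                rng.choice(bases, size=max(tail_len - len(spec.anchor_suffix), 0))
            ))[:max(tail_len, 0)]
            read = np.array(list(head + spacer + tail))
            if error_rate > 0:
                hit = rng.random(read.size) < error_rate
                if hit.any():
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    codes = {b: i for i, b in enumerate("ACGT")}
                    orig = np.array([codes[b] for b in read[hit]])
                    read[hit] = bases[(orig + shift) % 4]
            seq = "".join(read)
            lines.append(f"@read{ridx} {guide_id}")
            lines.append(seq)
            lines.append("+")
            lines.append("I" * len(seq))
    text = "\n".join(lines) + ("\n" if lines else "")
    if out is None:
        return text
    if hasattr(out, "write"):
        out.write(text)
    else:
        with open(out, "w") as fh:
            fh.write(text)
    return None


def simulate_cell_guide_umis(
    n_cells: int,
    library: GuideLibrary,
    moi_mean: float = 0.7,
    signal_umi_mean: float = 20.0,
    ambient_umi_mean: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Simulate 5'-capture gRNA UMIs per cell with ambient background.

    Each cell receives Poisson(``moi_mean``) true guides (distinct,
    uniform over the library); true guides add Poisson(``signal_umi_mean``)
    UMIs on top of the ambient Poisson(``ambient_umi_mean``) every guide
    receives.  Returns the UMI matrix and the true assignments.
    """
    if min(moi_mean, signal_umi_mean) < 0 or ambient_umi_mean < 0:
        raise ValueError("rate parameters must be non-negative")
    rng = np.random.default_rng(seed)
    guide_ids = np.asarray(library.guide_ids)
    G = len(guide_ids)
    M = rng.poisson(ambient_umi_mean, size=(n_cells, G))
    truth: dict[str, set[str]] = {}
    barcodes = [f"cell{i + 1:05d}" for i in range(n_cells)]
    for i, bc in enumerate(barcodes):
        n_true = min(int(rng.poisson(moi_mean)), G)
        chosen = rng.choice(G, size=n_true, replace=False)
        M[i, chosen] += rng.poisson(signal_umi_mean, size=n_true)
        truth[bc] = set(guide_ids[chosen])
    umi = pd.DataFrame(M, index=barcodes, columns=guide_ids)
    return umi, truth


def simulate_nt_pvalues(
    n: int, a: float = 1.0, b: float = 1.0, seed: int = 0
) -> np.ndarray:
    """i.i.d. Beta(a, b) draws: a miscalibrated (or, at a=b=1, uniform)
    null for stressing the NT calibration."""
    if n < 10:
        raise ValueError("n must be >= 10")
    if min(a, b) <= 0:
        raise ValueError("Beta shapes must be positive")
    rng = np.random.default_rng(seed)
    return rng.beta(a, b, size=n)


def config_from_yaml(path) -> ScreenSimConfig:
    """Load a ScreenSimConfig from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ScreenSimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ScreenSimConfig(**raw)
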