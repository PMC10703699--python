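"""sortscreen: design and analysis of FACS sort-based pooled CRISPR screens.

The analysis path runs guide library design (:mod:`sortscreen.library`),
spacer counting (:mod:`sortscreen.quantify`), paired negative-binomial
guide enrichment (:mod:`sortscreen.enrich`), and NT-calibrated
robust-rank-aggregation gene inference (:mod:`sortscreen.geneagg`), with a
ground-truth simulator (:mod:`sortscreen.synth`) and single-cell guide
assignment (:mod:`sortscreen.sc_assign`).
"""

from .enrich import (
    GuideEnrichment,
    GuideEnrichmentResults,
    bh_adjust,
    size_factors,
)
from .geneagg import (
    GeneAggregation,
    GeneAggregationResults,
    build_calibration,
    build_null_table,
    gene_effect_sizes,
    partition_ntc,
    rra_rho,
)
from .library import (
    NON_TARGETING,
    GuideLibrary,
    GuideRecord,
    design_tiling_library,
    filter_off_target,
    generate_nt_guides,
    scan_candidate_guides,
    validate_library,
)
from .quantify import (
    CountMatrix,
    ReadExtractionSpec,
    build_spacer_index,
    count_fastq,
    coverage_report,
)
from .sc_assign import (
    assign_guides,
    concordance_rates,
    marker_response_test,
    qc_filter_cells,
)
from .synth import (
    ScreenSimConfig,
    expected_log2fc,
    simulate_cell_guide_umis,
    simulate_fastq,
    simulate_nt_pvalues,
    simulate_sort_screen,
    synthetic_library,
)

__version__ = "1.0.0"


def analyze_screen(
    count_matrix,
    gene_map=None,
    n_sim: int = 10_000_000,
    seed: int = 0,
    fdr: float = 0.05,
    weight_mode: str = "one_minus_p",
):
    """Run the full sorted-bin screen analysis on a count matrix.

    Convenience wrapper: fits :class:`GuideEnrichment` then
    :class:`GeneAggregation` and returns both results objects.
    """
    enr = GuideEnrichment(
        count_matrix.counts, count_matrix.samples, gene_map=gene_map
    ).fit()
    agg = GeneAggregation.from_results(
        enr, gene_map=gene_map, n_sim=n_sim, seed=seed, fdr=fdr,
        weight_mode=weight_mode,
    ).fit()
    return enr, agg
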