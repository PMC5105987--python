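"""Default configuration values used throughout the pipeline.

These are the operating points of the method: preprocessing filters, the
genomic window used to attach loci to genes, the hop bound of the network
search, the cross-validation layout and the regularization grids. They are
collected in one frozen snapshot so they can be asserted and audited in one
place.
"""

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class Defaults:
    #: loci with minor allele frequency <= this fraction are removed
    maf_threshold: float = 0.05
    #: loci with single-locus allelic-association p below this are excluded
    #: before locus-set discovery, to avoid sets driven by one marginal hit
    marginal_exclusion_alpha: float = 1e-7
    #: half-width of the region of interest around a gene's coding region (bp)
    roi_window_bp: int = 50_000
    #: maximum number of network hops between loci recruited into one set
    hop_bound: int = 3
    #: fraction of case samples a complete locus set must cover
    coverage_fraction: float = 1.0
    #: outer (and inner) cross-validation folds
    n_folds: int = 5
    #: number of fold randomizations averaged in reports
    n_repeats: int = 5
    #: L1 penalty weight of the risk model
    lasso_lambda: float = 0.001
    #: significance thresholds swept during filtering-based feature selection
    alpha_grid: tuple = (5e-8, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
    #: L1 penalty weights searched in the inner cross-validation loop
    lambda_grid: tuple = (1e-4, 1e-3, 1e-2, 1e-1)
    #: L2 stabilizer added to non-intercept coefficients of the joint
    #: feature-filtering logistic regression (ill-posed when q >> n)
    regression_filter_ridge: float = 1e-4
    #: report this many genes in the gene-frequency summary
    gene_report_top_k: int = 10

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULTS = Defaults()
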