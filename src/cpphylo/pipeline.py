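"""End-to-end desk-scale study on a synthetic multi-gene dataset.

Mirrors the full analysis chain: simulate a known-truth dataset, infer the
ML tree from the concatenation, optimize the GTR+Gamma model on it, measure
per-gene relative rates, partition genes into rate categories, and run the
bootstrap data-requirement experiment overall and per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment_stats import summarize_alignment
from .datareq import DESK_SIZES, category_requirement_curves, data_requirement_curve
from .gene_rates import categorize_genes, compute_gene_rates, concatenate_category
from .likelihood import fit_model_and_branch_lengths
from .model import SubstModel, empirical_base_freqs
from .search import search_ml_tree
from .seeding import child_seed
from .simulate import SimConfig, simulate_dataset


@dataclass
class StudyResult:
    sim: object
    ml_tree: object
    model: SubstModel
    log_likelihood: float
    summary: object
    records: list
    category_alignments: dict = field(default_factory=dict)
    curve_all: list = field(default_factory=list)
    curve_categories: list = field(default_factory=list)


def infer_reference(alignment, seed, n_starts: int = 1):
    """ML tree + fitted GTR+Gamma model for a concatenated alignment.

    One randomized parsimony start + NNI by default (the desk-scale knob);
    model parameters and branch lengths are then optimized on the final
    topology.
    """
    search_model = SubstModel(base_freqs=empirical_base_freqs(alignment))
    tree = search_ml_tree(alignment, search_model, n_starts=n_starts, seed=seed)
    tree, model, logl = fit_model_and_branch_lengths(alignment, tree, search_model)
    return tree, model, logl


def run_study(
    config: SimConfig,
    sizes=DESK_SIZES,
    n_replicates: int = 3,
    n_boot: int = 30,
    category_sizes=(2500,),
    min_gene_length: int = 800,
    n_starts: int = 1,
    run_curves: bool = True,
) -> StudyResult:
    """Run the full pipeline; every random stream derives from config.seed."""
    sim = simulate_dataset(config)
    tree, model, logl = infer_reference(sim.alignment, child_seed(config.seed, 10), n_starts)
    summary = summarize_alignment(sim.alignment)

    records = categorize_genes(
        compute_gene_rates(sim.alignment, tree, model), min_length=min_gene_length
    )
    gene_alns = {p.name: sim.alignment.gene_slice(p) for p in sim.alignment.partitions}
    cats = {}
    for cat in ("slow", "medium", "fast"):
        if any(r.category == cat for r in records):
            cats[cat] = concatenate_category(records, gene_alns, cat)

    result = StudyResult(sim, tree, model, logl, summary, records, cats)
    if run_curves:
        result.curve_all = data_requirement_curve(
            sim.alignment, tree, model, sizes, n_replicates, n_boot,
            child_seed(config.seed, 11), source="all",
        )
        result.curve_categories = category_requirement_curves(
            cats, tree, model, category_sizes, n_replicates, n_boot,
            child_seed(config.seed, 12),
        )
    return result
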