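"""Data-requirement curves: bootstrap support as a function of alignment size.

For each target size, datasets of exactly that many columns are drawn with
replacement from the source alignment; each is analysed by ML (one
randomized parsimony start + NNI under the supplied model), and support is
counted on the fixed reference topology's bipartitions.  The summaries are
the proportion of reference branches exceeding 90% support (strict) and at
exactly 100%.  The same machinery runs per rate category to compare how
quickly slow, medium and fast genes accumulate support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .alignment import Alignment
from .bootstrap import bipartition_support, subsample_columns
from .model import SubstModel
from .search import nni_search
from .parsimony import parsimony_random_addition_tree
from .seeding import child_seed, rng_for
from .tree import Tree, prune_to

log = logging.getLogger(__name__)

DESK_SIZES = (1000, 2500, 5000, 10000)
PAPER_SIZES = (1000, 2500, 5000, 10000, 25000, 50000, 100000)


@dataclass
class SupportResult:
    """Support on the reference topology for one (source, size, replicate)."""

    source: str
    size: int
    replicate: int
    supports: dict = field(repr=False)
    prop_ge90: float = 0.0
    prop_eq100: float = 0.0

    def __post_init__(self):
        vals = list(self.supports.values())
        if vals:
            self.prop_ge90 = sum(v > 90.0 for v in vals) / len(vals)
            self.prop_eq100 = sum(v == 100.0 for v in vals) / len(vals)


def support_for_size(
    alignment: Alignment,
    ref_topology: Tree,
    model: SubstModel,
    size: int,
    n_boot: int,
    seed,
    source: str = "all",
    replicate: int = 0,
    tol: float = 1e-3,
) -> SupportResult:
    """One replicate: ``n_boot`` subsampled datasets of ``size`` columns,
    each analysed by ML, summarized as support on the reference topology."""
    if n_boot < 1:
        raise ValueError("need at least one bootstrap dataset")
    if set(ref_topology.taxa) != set(alignment.taxa):
        ref_topology = prune_to(ref_topology, set(alignment.taxa) & set(ref_topology.taxa))
    trees = []
    for b in range(n_boot):
        sub = subsample_columns(alignment, size, rng_for(seed, 0, b))
        try:
            start = parsimony_random_addition_tree(sub, child_seed(seed, 1, b))
            trees.append(nni_search(sub, start, model, tol=tol))
        except Exception:  # pragma: no cover - defensive
            log.exception("inference failed on bootstrap %d; skipping", b)
    supports = bipartition_support(ref_topology, trees)
    return SupportResult(source, size, replicate, supports)


def data_requirement_curve(
    alignment: Alignment,
    ref_topology: Tree,
    model: SubstModel,
    sizes=DESK_SIZES,
    n_replicates: int = 3,
    n_boot: int = 30,
    seed: int = 0,
    source: str = "all",
) -> list[SupportResult]:
    """The full subsampling experiment for one source alignment."""
    if not sizes:
        raise ValueError("no alignment sizes given")
    results = []
    for si, size in enumerate(sizes):
        for rep in range(n_replicates):
            results.append(
                support_for_size(
                    alignment,
                    ref_topology,
                    model,
                    size,
                    n_boot,
                    rng_for(seed, si, rep),
                    source=source,
                    replicate=rep,
                )
            )
    return results


def category_requirement_curves(
    category_alignments: dict,
    ref_topology: Tree,
    model: SubstModel,
    sizes=DESK_SIZES,
    n_replicates: int = 3,
    n_boot: int = 30,
    seed: int = 0,
) -> list[SupportResult]:
    """Per-rate-category curves (slow / medium / fast) on shared machinery."""
    results = []
    for ci, name in enumerate(sorted(category_alignments)):
        aln = category_alignments[name]
        if aln is None or aln.n_sites == 0:
            raise ValueError(f"rate category {name!r} has no alignment columns")
        results.extend(
            data_requirement_curve(
                aln,
                ref_topology,
                model,
                sizes,
                n_replicates,
                n_boot,
                child_seed(seed, 7, ci),
                source=name,
            )
        )
    return results


def results_table(results) -> pd.DataFrame:
    """Long-form per-replicate table (one row per source x size x replicate)."""
    return pd.DataFrame(
        {
            "source": [r.source for r in results],
            "size": [r.size for r in results],
            "replicate": [r.replicate for r in results],
            "prop_ge90": [r.prop_ge90 for r in results],
            "prop_eq100": [r.prop_eq100 for r in results],
        }
    )


def branch_support_table(results) -> pd.DataFrame:
    """Per-branch long-form table (source, size, replicate, branch, support)."""
    rows = []
    for r in results:
        for split, sup in sorted(r.supports.items(), key=lambda kv: tuple(sorted(kv[0]))):
            rows.append(
                {
                    "source": r.source,
                    "size": r.size,
                    "replicate": r.replicate,
                    "branch": "|".join(sorted(split)),
                    "support": sup,
                }
            )
    return pd.DataFrame(rows)


def summarize_curve(results) -> pd.DataFrame:
    """Mean and range of the support summaries per source and size."""
    df = results_table(results)
    return (
        df.groupby(["source", "size"])
        .agg(
            mean_prop_ge90=("prop_ge90", "mean"),
            min_prop_ge90=("prop_ge90", "min"),
            max_prop_ge90=("prop_ge90", "max"),
            mean_prop_eq100=("prop_eq100", "mean"),
        )
        .reset_index()
    )


def plot_curves(results, path) -> None:
    """Support-vs-size plot, one panel per summary, one line per source."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize_curve(results)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, col, title in zip(
        axes, ["mean_prop_ge90", "mean_prop_eq100"], [">90% support", "100% support"]
    ):
        for source, grp in summary.groupby("source"):
            ax.plot(grp["size"], grp[col], marker="o", label=source)
        ax.set_xlabel("alignment size (nt)")
        ax.set_title(title)
    axes[0].set_ylabel("proportion of reference branches")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
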