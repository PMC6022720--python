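"""Haplogroup assignment by recursive descent with an accumulator.

A sample's genotypes enter at the tree root.  Walking down the tree, each
node contributes its required (position, allele) genotypes to an
*effective* requirement map, with a descendant's requirement overriding an
ancestor's at the same position — this realizes reversions (e.g. the
10398 back-mutation on the J and K branches) without a separate data
structure.  A node whose effective map is fully matched enters the
accumulator.  A subtree is pruned only when some unmet requirement can
never be overridden inside it, so a reversion branch stays reachable while
ordinary mismatches stop the descent exactly as a plain recursive check
would.

Accumulated haplogroups are then ranked by their distance from the root:
a longer path means more SNPs checked, hence a more specific call.  Only
the deepest haplogroup(s) survive; if nothing beyond the root is
satisfied, the sample is unclassified.

A missing call never satisfies a requirement: missingness is not
evidence, so samples missing key SNPs near the top of the tree come out
unclassified rather than misassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .genotype_io import MISSING, SampleGenotypes
from .tree_model import HaplogroupNode, HaplogroupTree

logger = logging.getLogger(__name__)

STATUS_CLASSIFIED = "classified"
STATUS_UNCLASSIFIED = "unclassified"


@dataclass
class ClassificationResult:
    """Assignment for one sample.

    ``haplogroups`` usually holds a single label; several only when
    distinct nodes tie at the maximal depth.  ``paths`` holds the
    root-to-node label path for each reported haplogroup, in the same
    order.  ``missing_required`` lists panel positions that were missing
    in the sample and are required by some tree node — the raw material
    for missing-data failure analysis.
    """

    sample_id: str
    haplogroups: list[str] = field(default_factory=list)
    paths: list[list[str]] = field(default_factory=list)
    status: str = STATUS_UNCLASSIFIED
    missing_required: list[int] = field(default_factory=list)

    @property
    def is_classified(self) -> bool:
        return self.status == STATUS_CLASSIFIED


def node_satisfied(node: HaplogroupNode, calls: SampleGenotypes) -> bool:
    """Does the sample carry every genotype this node itself requires?

    Only the node's own requirement list is checked; ancestry is the
    caller's concern.  Missing or mismatching calls fail the node.
    """
    return all(
        calls.calls.get(position) == allele
        for position, allele in node.required_genotypes
    )


def rank_accumulator(
    tree: HaplogroupTree, accumulated: Sequence[str]
) -> list[str]:
    """Keep only the accumulated labels at maximal distance from the root.

    Output order is tree-definition order, which makes ties
    deterministic.  An empty accumulator yields an empty list.
    """
    depths = {label: tree.depth(label) for label in accumulated}  # KeyError on unknown
    if not depths:
        return []
    deepest = max(depths.values())
    winners = {label for label, d in depths.items() if d == deepest}
    return [name for name in tree.nodes if name in winners]


def classify_sample(
    tree: HaplogroupTree, sample: SampleGenotypes
) -> ClassificationResult:
    """Assign the most specific haplogroup(s) supported by the calls."""
    calls = sample.calls
    accumulator: list[str] = []

    def descend(node: HaplogroupNode, inherited: dict[int, str]) -> None:
        effective = dict(inherited)
        effective.update(node.required_genotypes)
        unmet = {
            position
            for position, allele in effective.items()
            if calls.get(position) != allele
        }
        if not unmet:
            accumulator.append(node.name)
        for child in node.children:
            # descend only while every unmet requirement could still be
            # overridden (re-required) somewhere inside the child's subtree
            if unmet <= tree.subtree_required_positions(child.name):
                descend(child, effective)

    descend(tree.root, {})

    ranked = rank_accumulator(tree, accumulator)
    haplogroups = [label for label in ranked if label != tree.root.name]

    required_anywhere = set()
    for node in tree:
        required_anywhere.update(p for p, _ in node.required_genotypes)
    missing_required = sorted(
        p for p in required_anywhere if calls.get(p) is MISSING or p not in calls
    )

    if haplogroups:
        return ClassificationResult(
            sample_id=sample.sample_id,
            haplogroups=haplogroups,
            paths=[tree.path_to_root(label) for label in haplogroups],
            status=STATUS_CLASSIFIED,
            missing_required=missing_required,
        )
    return ClassificationResult(
        sample_id=sample.sample_id,
        status=STATUS_UNCLASSIFIED,
        missing_required=missing_required,
    )


def classify_dataset(
    tree: HaplogroupTree, samples: Sequence[SampleGenotypes]
) -> list[ClassificationResult]:
    """Classify every sample, preserving input order.

    A per-sample failure is recorded as an unclassified result and logged
    instead of aborting the batch.
    """
    results: list[ClassificationResult] = []
    for sample in samples:
        try:
            results.append(classify_sample(tree, sample))
        except Exception:  # pragma: no cover - classify_sample is total
            logger.exception(
                "classification failed for sample %s", sample.sample_id
            )
            results.append(
                ClassificationResult(
                    sample_id=sample.sample_id, status=STATUS_UNCLASSIFIED
                )
            )
    n_classified = sum(r.is_classified for r in results)
    logger.info(
        "classified %d/%d samples (%d unclassified)",
        n_classified, len(results), len(results) - n_classified,
    )
    return results
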