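"""Comparison of haplogroup call sets and founder frequency summaries.

Two call sets agree on a sample when they name the same haplogroup, *even
if one method resolved it more finely* (A2 vs A2x): tools built on the
full Phylotree emit sub-haplogroup labels the reduced tree cannot.  The
finer-resolution rule is applied tree-aware first — two labels present in
the reduced tree are concordant iff they lie on one root-to-node path —
and falls back to a string rule for foreign labels: one label must extend
the other and the first extra character must continue the Phylotree
letter/digit alternation ("A2" + "x" extends; "H" + "V" does not, since
HV is not a sub-haplogroup of H).

Samples unclassified in either call set are excluded from the denominator
before percent concordance is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classifier import ClassificationResult
from .genotype_io import SampleGenotypes
from .tree_model import HaplogroupTree

logger = logging.getLogger(__name__)

#: Labels treated as "no call" (case-insensitive).
UNCLASSIFIED_LABELS = frozenset({"unclassified", "unknown", "", "na", "none"})


@dataclass(frozen=True)
class CallSet:
    """One tool's haplogroup assignments: sample_id -> free-text label."""

    calls: Mapping[str, str]
    source: str = ""

    @classmethod
    def from_csv(cls, path: str | Path, source: str | None = None) -> "CallSet":
        """Read a two-column CSV (header ``sample_id,haplogroup``)."""
        frame = pd.read_csv(path, dtype=str)
        missing = {"sample_id", "haplogroup"} - set(frame.columns)
        if missing:
            raise ValueError(
                f"{path}: call-set CSV must have columns "
                f"'sample_id' and 'haplogroup' (missing {sorted(missing)})"
            )
        calls = dict(
            zip(frame["sample_id"], frame["haplogroup"].fillna(""))
        )
        return cls(calls=calls, source=source or str(path))

    @classmethod
    def from_results(
        cls, results: Sequence[ClassificationResult], source: str = "mitoclass"
    ) -> "CallSet":
        """Collapse classifier output to labels; ties join with ';'."""
        return cls(
            calls={
                r.sample_id: ";".join(r.haplogroups) if r.haplogroups
                else "unclassified"
                for r in results
            },
            source=source,
        )


@dataclass
class ConcordanceReport:
    """Pairwise agreement summary after unclassified exclusion."""

    source_a: str
    source_b: str
    n_shared: int
    n_excluded_unclassified: int
    n_compared: int
    n_concordant: int
    discordant: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def percent_concordant(self) -> float:
        return 100.0 * self.n_concordant / self.n_compared

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source_a": self.source_a,
                    "source_b": self.source_b,
                    "n_shared": self.n_shared,
                    "n_excluded_unclassified": self.n_excluded_unclassified,
                    "n_compared": self.n_compared,
                    "n_concordant": self.n_concordant,
                    "percent_concordant": round(self.percent_concordant, 1),
                }
            ]
        )


def _normalize(label: str) -> str:
    return str(label).strip()


def is_unclassified(label: str) -> bool:
    return _normalize(label).lower() in UNCLASSIFIED_LABELS


def _alternation_extends(longer: str, shorter: str) -> bool:
    """Does ``longer`` extend ``shorter`` as a finer Phylotree label?

    Phylotree labels alternate letter and digit runs (A -> A2 -> A2x); a
    valid extension therefore switches character class at the boundary.
    This blocks false nestings like "H" -> "HV".
    """
    if not longer.startswith(shorter) or longer == shorter:
        return False
    boundary, last = longer[len(shorter)], shorter[-1]
    return last.isdigit() != boundary.isdigit()


def is_concordant(label_a: str, label_b: str, tree: HaplogroupTree) -> bool:
    """Same haplogroup, tolerating finer resolution on either side."""
    a, b = _normalize(label_a), _normalize(label_b)
    if a == b:
        return True
    if a in tree.nodes and b in tree.nodes:
        # both are reduced-tree haplogroups: concordant iff nested
        return a in tree.path_to_root(b) or b in tree.path_to_root(a)
    return _alternation_extends(a, b) or _alternation_extends(b, a)


def concordance_table(
    a: CallSet, b: CallSet, tree: HaplogroupTree
) -> ConcordanceReport:
    """Agreement between two call sets over their shared samples.

    Samples with an unclassified/unknown label in either set are excluded
    and counted separately.  Raises if the two sets share no samples or if
    every shared sample is excluded.
    """
    shared = sorted(set(a.calls) & set(b.calls))
    if not shared:
        raise ValueError(
            f"call sets {a.source!r} and {b.source!r} share no samples"
        )
    excluded = [
        s for s in shared
        if is_unclassified(a.calls[s]) or is_unclassified(b.calls[s])
    ]
    compared = [s for s in shared if s not in set(excluded)]
    if not compared:
        raise ValueError("no comparable samples (all shared samples unclassified)")
    discordant = [
        (s, _normalize(a.calls[s]), _normalize(b.calls[s]))
        for s in compared
        if not is_concordant(a.calls[s], b.calls[s], tree)
    ]
    report = ConcordanceReport(
        source_a=a.source,
        source_b=b.source,
        n_shared=len(shared),
        n_excluded_unclassified=len(excluded),
        n_compared=len(compared),
        n_concordant=len(compared) - len(discordant),
        discordant=discordant,
    )
    logger.info(
        "concordance %s vs %s: %.1f%% (%d/%d compared, %d excluded)",
        report.source_a, report.source_b, report.percent_concordant,
        report.n_concordant, report.n_compared, report.n_excluded_unclassified,
    )
    return report


def _founder_ids(samples: Sequence[SampleGenotypes]) -> set[str]:
    """Sample ids that are not the offspring of another sample.

    Offspring are detected through the PED maternal-id column: a sample
    whose maternal_id names another individual in the same family is a
    child.  If no pedigree structure is present the filter is a no-op.
    """
    present = {(s.family_id, s.individual_id) for s in samples}
    founders = {
        s.sample_id
        for s in samples
        if s.maternal_id in ("", "0")
        or (s.family_id, s.maternal_id) not in present
    }
    if len(founders) == len(samples):
        logger.warning(
            "founders-only filter: no offspring detected (no pedigree "
            "structure in PED columns); keeping all samples"
        )
    return founders


def haplogroup_frequencies(
    results: Sequence[ClassificationResult],
    samples: Sequence[SampleGenotypes],
    tree: HaplogroupTree,
    founders_only: bool = True,
) -> tuple[dict[str, float], dict[str, float]]:
    """Haplogroup and lineage frequency distributions.

    Offspring (maternal-id linkage) are excluded when ``founders_only``,
    since a child's mtDNA duplicates its mother's; unclassified samples
    are excluded from the denominator.  Tied multi-label calls contribute
    their first (most tree-senior) label.  Both distributions sum to 1
    when non-empty; lineage frequencies are exact sums of their member
    haplogroup frequencies.
    """
    by_id = {s.sample_id: s for s in samples}
    result_ids = {r.sample_id for r in results}
    if not result_ids <= set(by_id):
        raise ValueError(
            f"results reference samples absent from the sample list: "
            f"{sorted(result_ids - set(by_id))[:5]}"
        )
    keep = _founder_ids(samples) if founders_only else {s.sample_id for s in samples}
    counts: dict[str, int] = {}
    for r in results:
        if r.sample_id in keep and r.is_classified:
            label = r.haplogroups[0]
            counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    if total == 0:
        logger.warning("no classified founder samples; empty frequency table")
        return {}, {}
    label_freq = {label: n / total for label, n in counts.items()}
    lineage_freq: dict[str, float] = {}
    for label, freq in label_freq.items():
        lineage = tree.node(label).lineage
        lineage_freq[lineage] = lineage_freq.get(lineage, 0.0) + freq
    return label_freq, lineage_freq


def frequency_table(
    results: Sequence[ClassificationResult],
    samples: Sequence[SampleGenotypes],
    tree: HaplogroupTree,
    founders_only: bool = True,
) -> pd.DataFrame:
    """Frequency summary as a DataFrame (label, count, frequency, lineage)."""
    label_freq, _ = haplogroup_frequencies(
        results, samples, tree, founders_only=founders_only
    )
    # recover integer counts with the same denominator rules
    keep = _founder_ids(samples) if founders_only else {
        s.sample_id for s in samples
    }
    counts: dict[str, int] = {}
    for r in results:
        if r.sample_id in keep and r.is_classified:
            counts[r.haplogroups[0]] = counts.get(r.haplogroups[0], 0) + 1
    rows = [
        {
            "haplogroup": label,
            "count": counts[label],
            "frequency": label_freq[label],
            "lineage": tree.node(label).lineage,
        }
        for label in sorted(label_freq, key=lambda l: (-counts[l], l))
    ]
    return pd.DataFrame(rows)
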