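"""Ground-truth-labeled synthetic panel genotypes.

The generator inverts the classifier: a sample "of" haplogroup X carries
exactly the cumulative required alleles on the root->X path (descendant
override at reversion positions) and the panel's ancestral allele at every
other position.  Noise is layered on top: per-call i.i.d. missingness,
per-call discordant diploid pairs (which read back as missing), and an
optional per-marker knockout that blanks a marker in every sample — the
pattern real assay failures produce.

Trios mirror a family-based study design: the child copies the mother's
haplotype, so founder-only frequency analyses are testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    MapMarker,
    MarkerMap,
    SampleGenotypes,
    write_dataset,
)
from .tree_model import HaplogroupTree


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    missing_rate and discordant_rate are per-call probabilities; a
    discordant call is emitted in PED output as a mismatched allele pair
    and is missing in memory.  ``n_trios`` leading families are
    father/mother/child trios (child duplicates the maternal haplotype);
    the rest are unrelated singletons.  ``knockout_markers`` lists rCRS
    positions blanked in every sample.
    """

    n_samples: int
    haplogroup_weights: Mapping[str, float] | None = None
    missing_rate: float = 0.0
    discordant_rate: float = 0.0
    n_trios: int = 0
    seed: int = 0
    knockout_markers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for name in ("missing_rate", "discordant_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n_trios < 0 or 3 * self.n_trios > self.n_samples:
            raise ValueError(
                f"n_trios={self.n_trios} needs {3 * self.n_trios} samples "
                f"but n_samples={self.n_samples}"
            )
        if self.haplogroup_weights is not None:
            weights = dict(self.haplogroup_weights)
            if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ValueError(
                    "haplogroup_weights must be non-negative with positive sum"
                )


def panel_marker_map(tree: HaplogroupTree) -> MarkerMap:
    """MAP-file view of the panel: chromosome 26, ascending rCRS order."""
    return MarkerMap(
        tuple(
            MapMarker("26", tree.panel[p].name, 0.0, p)
            for p in tree.panel_positions()
        )
    )


def genotypes_for_haplogroup(
    tree: HaplogroupTree,
    label: str,
    family_id: str = "FAM1",
    individual_id: str = "IND1",
) -> SampleGenotypes:
    """The noise-free genotype vector that defines haplogroup ``label``.

    Cumulative required alleles down the root->label path, ancestral
    alleles everywhere else, nothing missing.
    """
    calls: dict[int, str | None] = {
        p: tree.panel[p].ancestral_allele for p in tree.panel_positions()
    }
    calls.update(dict(tree.required_genotypes_cumulative(label)))
    return SampleGenotypes(
        family_id=family_id, individual_id=individual_id, calls=calls
    )


def _draw_labels(
    tree: HaplogroupTree, config: SimulationConfig, rng: np.random.Generator, n: int
) -> list[str]:
    if config.haplogroup_weights is None:
        labels = tree.terminal_nodes()
        weights = np.ones(len(labels))
    else:
        labels = list(config.haplogroup_weights)
        for label in labels:
            tree.node(label)  # raise on unknown
        weights = np.asarray(
            [config.haplogroup_weights[l] for l in labels], dtype=float
        )
    probs = weights / weights.sum()
    return [labels[i] for i in rng.choice(len(labels), size=n, p=probs)]


def _apply_noise(
    sample: SampleGenotypes,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    alleles = np.array(list("ACGT"))
    for position in list(sample.calls):
        if position in config.knockout_markers:
            sample.calls[position] = MISSING
            continue
        if rng.random() < config.missing_rate:
            sample.calls[position] = MISSING
        elif rng.random() < config.discordant_rate:
            true_allele = sample.calls[position]
            others = [a for a in alleles if a != true_allele]
            other = others[rng.integers(len(others))]
            sample.discordant_pairs[position] = (true_allele, other)
            sample.calls[position] = MISSING


def simulate_dataset(
    tree: HaplogroupTree, config: SimulationConfig
) -> tuple[list[SampleGenotypes], dict[str, str]]:
    """Draw a labeled dataset; reproducible for a given seed.

    Returns the samples and a truth table ``sample_id -> haplogroup``.
    Trio children inherit the mother's haplotype and truth label before
    noise; noise is then injected independently per sample and call.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[SampleGenotypes] = []
    truth: dict[str, str] = {}

    n_trio_members = 3 * config.n_trios
    n_singletons = config.n_samples - n_trio_members
    founder_labels = _draw_labels(
        tree, config, rng, 2 * config.n_trios + n_singletons
    )
    label_iter = iter(founder_labels)

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"IND{counter:04d}"

    for t in range(1, config.n_trios + 1):
        fam = f"FAM{t:04d}"
        father_label, mother_label = next(label_iter), next(label_iter)
        father = genotypes_for_haplogroup(tree, father_label, fam, next_id())
        father.sex_code = "1"
        mother = genotypes_for_haplogroup(tree, mother_label, fam, next_id())
        mother.sex_code = "2"
        child = genotypes_for_haplogroup(tree, mother_label, fam, next_id())
        child.paternal_id = father.individual_id
        child.maternal_id = mother.individual_id
        child.sex_code = str(rng.integers(1, 3))
        for member, label in (
            (father, father_label),
            (mother, mother_label),
            (child, mother_label),
        ):
            truth[member.sample_id] = label
            samples.append(member)

    for _ in range(n_singletons):
        label = next(label_iter)
        iid = next_id()
        sample = genotypes_for_haplogroup(tree, label, f"FAM{iid[3:]}", iid)
        sample.sex_code = str(rng.integers(1, 3))
        truth[sample.sample_id] = label
        samples.append(sample)

    for sample in samples:
        _apply_noise(sample, config, rng)
    return samples, truth


def write_fixture(
    samples: Sequence[SampleGenotypes],
    marker_map: MarkerMap,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write samples as a PED/MAP pair readable by :mod:`genotype_io`."""
    write_dataset(ped_path, map_path, marker_map, samples)


def write_truth_table(truth: Mapping[str, str], path: str | Path) -> None:
    """Truth labels as a two-column CSV (sample_id, haplogroup)."""
    pd.DataFrame(
        {"sample_id": list(truth), "haplogroup": list(truth.values())}
    ).to_csv(path, index=False, lineterminator="\n")
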