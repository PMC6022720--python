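"""PED/MAP genotype input and SNP call-rate QC.

mtDNA is haploid, but PED files store two allele tokens per marker; calls
are collapsed to a single allele on read.  Markers are joined to the panel
by rCRS position (the MAP bp column), never by marker name — names are
reporting sugar only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: Sentinel for a missing haploid call.
MISSING = None

VALID_TOKENS = frozenset("ACGT0")

#: Chromosome codes accepted as mitochondrial across PED dialects.
MT_CHROM_CODES = frozenset({"26", "MT", "M"})


class PedFormatError(ValueError):
    """Malformed PED/MAP content; message carries file and line number."""


@dataclass(frozen=True)
class MapMarker:
    """One MAP row: chromosome code, marker name, cM distance, bp position."""

    chromosome: str
    name: str
    genetic_distance: float
    position: int


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker list; order matches the PED allele-pair order."""

    markers: tuple[MapMarker, ...]

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[MapMarker]:
        return iter(self.markers)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.markers)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)


@dataclass
class SampleGenotypes:
    """One subject: the six PED pedigree columns plus haploid calls.

    ``calls`` maps rCRS position -> allele (A/C/G/T) or :data:`MISSING`.
    ``discordant_pairs`` remembers raw mismatched diploid pairs (read back
    as missing); it is excluded from equality so that write->read
    round-trips compare clean.
    """

    family_id: str
    individual_id: str
    paternal_id: str = "0"
    maternal_id: str = "0"
    sex_code: str = "0"
    phenotype_code: str = "-9"
    calls: dict[int, str | None] = field(default_factory=dict)
    discordant_pairs: dict[int, tuple[str, str]] = field(
        default_factory=dict, compare=False, repr=False
    )

    @property
    def sample_id(self) -> str:
        """Identifier used in result tables (the PED individual id)."""
        return self.individual_id

    def call_rate(self) -> float:
        if not self.calls:
            return 0.0
        n_called = sum(1 for a in self.calls.values() if a is not MISSING)
        return n_called / len(self.calls)


def collapse_diploid(
    allele1: str, allele2: str, *, context: str = ""
) -> str | None:
    """Collapse a diploid-encoded pair to one haploid allele.

    Equal non-zero tokens give that allele; ``0 0`` gives missing; a
    discordant non-zero pair (heteroplasmy-like or assay artifact) gives
    missing with a logged warning — picking either allele would fabricate
    a call.
    """
    a1, a2 = allele1.upper(), allele2.upper()
    for token in (a1, a2):
        if token not in VALID_TOKENS:
            raise PedFormatError(
                f"invalid allele token {token!r}{' at ' + context if context else ''}"
            )
    if a1 == "0" or a2 == "0":
        if a1 != a2:
            logger.warning(
                "half-missing genotype %s/%s%s treated as missing",
                a1, a2, " at " + context if context else "",
            )
        return MISSING
    if a1 != a2:
        logger.warning(
            "discordant alleles %s/%s%s treated as missing",
            a1, a2, " at " + context if context else "",
        )
        return MISSING
    return a1


def read_map(map_path: str | Path) -> MarkerMap:
    path = Path(map_path)
    markers: list[MapMarker] = []
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 4:
            raise PedFormatError(
                f"{path}:{lineno}: expected 4 MAP columns, found {len(fields)}"
            )
        chrom, name, dist, pos = fields
        try:
            marker = MapMarker(chrom, name, float(dist), int(pos))
        except ValueError as exc:
            raise PedFormatError(f"{path}:{lineno}: {exc}") from exc
        if chrom.upper() not in MT_CHROM_CODES:
            logger.warning(
                "%s:%d: marker %s has non-mitochondrial chromosome code %r",
                path, lineno, name, chrom,
            )
        markers.append(marker)
    positions = [m.position for m in markers]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise PedFormatError(f"{path}: duplicate marker positions {dupes}")
    return MarkerMap(tuple(markers))


def read_dataset(
    ped_path: str | Path, map_path: str | Path
) -> tuple[MarkerMap, list[SampleGenotypes]]:
    """Read a PED/MAP pair into haploid in-memory genotypes."""
    marker_map = read_map(map_path)
    path = Path(ped_path)
    expected = 6 + 2 * len(marker_map)
    samples: list[SampleGenotypes] = []
    seen_ids: set[tuple[str, str]] = set()
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != expected:
            raise PedFormatError(
                f"{path}:{lineno}: expected {expected} fields "
                f"(6 + 2x{len(marker_map)} markers), found {len(fields)}"
            )
        fid, iid, pat, mat, sex, pheno = fields[:6]
        if (fid, iid) in seen_ids:
            raise PedFormatError(
                f"{path}:{lineno}: duplicate sample id {fid} {iid}"
            )
        seen_ids.add((fid, iid))
        calls: dict[int, str | None] = {}
        discordant: dict[int, tuple[str, str]] = {}
        for marker, k in zip(marker_map, range(6, expected, 2)):
            a1, a2 = fields[k].upper(), fields[k + 1].upper()
            try:
                call = collapse_diploid(
                    a1, a2, context=f"{path}:{lineno} marker {marker.name}"
                )
            except PedFormatError as exc:
                raise PedFormatError(str(exc)) from None
            calls[marker.position] = call
            if call is MISSING and "0" not in (a1, a2):
                discordant[marker.position] = (a1, a2)
        samples.append(
            SampleGenotypes(
                family_id=fid,
                individual_id=iid,
                paternal_id=pat,
                maternal_id=mat,
                sex_code=sex,
                phenotype_code=pheno,
                calls=calls,
                discordant_pairs=discordant,
            )
        )
    return marker_map, samples


def write_dataset(
    ped_path: str | Path,
    map_path: str | Path,
    marker_map: MarkerMap,
    samples: Sequence[SampleGenotypes],
) -> None:
    """Write samples back to a PED/MAP pair (haploid calls as homozygous
    pairs, missing as ``0 0``, recorded discordant pairs verbatim)."""
    with open(map_path, "w", encoding="utf-8") as fh:
        for m in marker_map:
            dist = int(m.genetic_distance) if m.genetic_distance == int(
                m.genetic_distance
            ) else m.genetic_distance
            fh.write(f"{m.chromosome}\t{m.name}\t{dist}\t{m.position}\n")
    with open(ped_path, "w", encoding="utf-8") as fh:
        for s in samples:
            row = [
                s.family_id, s.individual_id, s.paternal_id,
                s.maternal_id, s.sex_code, s.phenotype_code,
            ]
            for m in marker_map:
                if m.position in s.discordant_pairs:
                    a1, a2 = s.discordant_pairs[m.position]
                elif s.calls.get(m.position) is MISSING:
                    a1 = a2 = "0"
                else:
                    a1 = a2 = s.calls[m.position]
                row.extend((a1, a2))
            fh.write("\t".join(row) + "\n")


def marker_call_rates(
    samples: Sequence[SampleGenotypes], marker_map: MarkerMap
) -> dict[int, float]:
    """Per-marker genotyping efficiency: called samples / all samples."""
    if not samples:
        raise ValueError("at least one sample required to compute call rates")
    n = len(samples)
    return {
        m.position: sum(
            1 for s in samples if s.calls.get(m.position) is not MISSING
        ) / n
        for m in marker_map
    }


def filter_by_call_rate(
    samples: Sequence[SampleGenotypes],
    marker_map: MarkerMap,
    threshold: float = 0.90,
) -> tuple[MarkerMap, list[str]]:
    """Drop markers whose genotyping efficiency is below ``threshold``.

    The boundary is inclusive: a marker called in exactly ``threshold`` of
    samples is retained.  Per-sample calls are never modified; use
    :func:`restrict_to_markers` to mask dropped markers before
    classification.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    rates = marker_call_rates(samples, marker_map)
    retained = tuple(m for m in marker_map if rates[m.position] >= threshold)
    dropped = [m.name for m in marker_map if rates[m.position] < threshold]
    for m in marker_map:
        if m.name in dropped:
            logger.info(
                "QC: dropping marker %s (call rate %.3f < %.3f)",
                m.name, rates[m.position], threshold,
            )
    return MarkerMap(retained), dropped


def drop_blacklisted(
    marker_map: MarkerMap, panel: "dict[int, object]"
) -> tuple[MarkerMap, list[str]]:
    """Remove markers the panel blacklists, regardless of call rate."""
    bad_positions = {
        pos for pos, snp in panel.items() if getattr(snp, "in_qc_blacklist", False)
    }
    retained = tuple(m for m in marker_map if m.position not in bad_positions)
    dropped = [m.name for m in marker_map if m.position in bad_positions]
    if dropped:
        logger.info("QC: dropping blacklisted markers %s", ", ".join(dropped))
    return MarkerMap(retained), dropped


def restrict_to_markers(
    samples: Iterable[SampleGenotypes], marker_map: MarkerMap
) -> list[SampleGenotypes]:
    """Copies of samples with calls limited to the retained markers."""
    keep = set(marker_map.positions)
    out = []
    for s in samples:
        out.append(
            SampleGenotypes(
                family_id=s.family_id,
                individual_id=s.individual_id,
                paternal_id=s.paternal_id,
                maternal_id=s.maternal_id,
                sex_code=s.sex_code,
                phenotype_code=s.phenotype_code,
                calls={p: a for p, a in s.calls.items() if p in keep},
                discordant_pairs={
                    p: v for p, v in s.discordant_pairs.items() if p in keep
                },
            )
        )
    return out
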