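"""Reduced mitochondrial phylogeny and the SNP panel behind it.

The classifier's knowledge base is a small, hand-curated tree of common
mtDNA haplogroups (African L lineages, the M/N/R macrohaplogroups, and the
major European and Native American/Asian branches) together with a custom
panel of mitochondrial SNPs on the rCRS coordinate system.  Each node lists
the (position, allele) genotypes a sample must carry to belong to that
haplogroup, *in addition to* recursively satisfying its parent.  Back
mutations (reversions, e.g. the 10398 A->G reversion on the J and K
branches) are encoded as ordinary requirements that contradict an
ancestor's requirement; descendant requirements override ancestral ones
when the root-to-node requirements are accumulated.

The tree and panel ship as a single JSON document (see ``data/``) with a
``panel`` array and a ``nodes`` array in definition order (parents before
children).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Length of the revised Cambridge Reference Sequence (rCRS), in bp.
RCRS_LENGTH = 16_569

VALID_ALLELES = frozenset("ACGT")

#: Continental-ancestry tags used for frequency aggregation.  "Macro"
#: marks deep macrohaplogroup nodes (M, N, R) that are not themselves
#: reported as a continental lineage.
LINEAGES = frozenset({"African", "European", "NativeAmerican_Asian", "Macro"})

DEFAULT_TREE_RESOURCE = "default_tree.json"


class TreeConfigError(ValueError):
    """Malformed tree/panel configuration (parse-level problem)."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (cycle, orphan, unknown position, ...)."""


@dataclass(frozen=True)
class PanelSnp:
    """One marker of the genotyping panel.

    Parameters
    ----------
    name
        Marker label, conventionally ``"MT" + position`` (e.g. ``MT11251``).
    position
        1-based rCRS coordinate.
    ancestral_allele, derived_allele
        Single uppercase bases; *ancestral* is the state at the tree root
        (the mtDNA MRCA), not necessarily the rCRS base, since the rCRS
        itself belongs to haplogroup H.
    in_qc_blacklist
        True for markers excluded from classification by panel QC
        (hypervariable-region failure or NumtS cross-amplification).
    """

    name: str
    position: int
    ancestral_allele: str
    derived_allele: str
    in_qc_blacklist: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise TreeConfigError(
                f"panel SNP {self.name!r}: position {self.position} outside "
                f"rCRS range [1, {RCRS_LENGTH}]"
            )
        for label, allele in (
            ("ancestral", self.ancestral_allele),
            ("derived", self.derived_allele),
        ):
            if allele not in VALID_ALLELES:
                raise TreeConfigError(
                    f"panel SNP {self.name!r}: {label} allele {allele!r} "
                    "is not one of A/C/G/T"
                )
        if self.ancestral_allele == self.derived_allele:
            raise TreeConfigError(
                f"panel SNP {self.name!r}: ancestral and derived alleles "
                "are identical"
            )


@dataclass
class HaplogroupNode:
    """One haplogroup of the reduced tree."""

    name: str
    required_genotypes: tuple[tuple[int, str], ...]
    lineage: str
    parent: "HaplogroupNode | None" = None
    children: list["HaplogroupNode"] = field(default_factory=list)
    depth: int = 0

    def __repr__(self) -> str:  # keep reprs short; nodes are cyclic
        return f"HaplogroupNode({self.name!r}, depth={self.depth})"


class HaplogroupTree:
    """Validated reduced phylogeny plus its SNP panel.

    Nodes are kept in definition order (the order of the ``nodes`` array in
    the config file); this order is the deterministic tie-break used when
    several haplogroups end up equally specific.
    """

    def __init__(
        self,
        root: HaplogroupNode,
        nodes: "dict[str, HaplogroupNode]",
        panel: Iterable[PanelSnp],
    ) -> None:
        self.root = root
        self.nodes = dict(nodes)  # insertion order == definition order
        self.panel: dict[int, PanelSnp] = {}
        for snp in panel:
            if snp.position in self.panel:
                raise TreeConfigError(
                    f"duplicate panel position {snp.position} "
                    f"({self.panel[snp.position].name!r} and {snp.name!r})"
                )
            self.panel[snp.position] = snp
        self._subtree_positions: dict[str, frozenset[int]] = {}
        self._validate()
        self.lint()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0] is not self.root:
            raise TreeValidationError(
                f"tree must have exactly one parentless root; found "
                f"{[n.name for n in roots]}"
            )
        # reachability + acyclicity by walking child links from the root
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.name in seen:
                raise TreeValidationError(
                    f"cycle detected at node {node.name!r}"
                )
            seen.add(node.name)
            stack.extend(node.children)
        orphans = set(self.nodes) - seen
        if orphans:
            raise TreeValidationError(
                f"nodes not reachable from root: {sorted(orphans)}"
            )
        for node in self.nodes.values():
            if node.parent is not None:
                node.depth = node.parent.depth + 1
            for position, allele in node.required_genotypes:
                snp = self.panel.get(position)
                if snp is None:
                    raise TreeValidationError(
                        f"node {node.name!r} requires position {position}, "
                        "which is not in the panel"
                    )
                if allele not in (snp.ancestral_allele, snp.derived_allele):
                    raise TreeValidationError(
                        f"node {node.name!r} requires {position}{allele}, "
                        f"but panel SNP {snp.name!r} segregates "
                        f"{snp.ancestral_allele}/{snp.derived_allele}"
                    )
            if node.lineage not in LINEAGES:
                raise TreeValidationError(
                    f"node {node.name!r}: unknown lineage {node.lineage!r}"
                )
        self._index_subtrees()

    def _index_subtrees(self) -> None:
        """Positions required anywhere in each node's subtree (incl. itself).

        The classifier uses this to decide whether an unmet ancestral
        requirement can still be overridden deeper down (reversion
        handling), so pruning never cuts off a satisfiable node.
        """

        def collect(node: HaplogroupNode) -> frozenset[int]:
            positions = {p for p, _ in node.required_genotypes}
            for child in node.children:
                positions |= collect(child)
            out = frozenset(positions)
            self._subtree_positions[node.name] = out
            return out

        collect(self.root)

    def lint(self) -> list[str]:
        """Non-fatal consistency warnings (logged, also returned)."""
        warnings: list[str] = []
        for node in self.nodes.values():
            by_req: dict[frozenset, str] = {}
            for child in node.children:
                key = frozenset(self.required_genotypes_cumulative(child.name))
                if key in by_req:
                    warnings.append(
                        f"siblings {by_req[key]!r} and {child.name!r} have "
                        "identical cumulative requirements; classification "
                        "cannot separate them"
                    )
                by_req[key] = child.name
            for position, _ in node.required_genotypes:
                if self.panel[position].in_qc_blacklist:
                    warnings.append(
                        f"node {node.name!r} requires blacklisted marker "
                        f"{self.panel[position].name}"
                    )
        for message in warnings:
            logger.warning("tree lint: %s", message)
        return warnings

    # -- queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[HaplogroupNode]:
        return iter(self.nodes.values())

    @property
    def n_haplogroups(self) -> int:
        """Number of assignable haplogroup nodes (the root MRCA excluded)."""
        return len(self.nodes) - 1

    def node(self, name: str) -> HaplogroupNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise KeyError(f"unknown haplogroup label {name!r}") from None

    def depth(self, name: str) -> int:
        return self.node(name).depth

    def path_to_root(self, name: str) -> list[str]:
        """Labels from the root down to ``name``, inclusive."""
        node: HaplogroupNode | None = self.node(name)
        path: list[str] = []
        while node is not None:
            path.append(node.name)
            node = node.parent
        return path[::-1]

    def required_genotypes_cumulative(self, name: str) -> list[tuple[int, str]]:
        """Union of requirements along the root->node path.

        When an ancestor and a descendant require different alleles at the
        same position (a reversion), the descendant's allele wins; the
        position keeps its first-appearance rank in the returned list.
        """
        merged: dict[int, str] = {}
        for label in self.path_to_root(name):
            for position, allele in self.node(label).required_genotypes:
                merged[position] = allele
        return list(merged.items())

    def subtree_required_positions(self, name: str) -> frozenset[int]:
        self.node(name)  # raise on unknown label
        return self._subtree_positions[name]

    def terminal_nodes(self) -> list[str]:
        """Leaf haplogroup labels, in definition order."""
        return [n.name for n in self.nodes.values() if not n.children]

    def panel_positions(self) -> list[int]:
        """All panel positions in ascending rCRS order."""
        return sorted(self.panel)

    # -- (de)serialization ----------------------------------------------

    @classmethod
    def from_dict(cls, doc: Mapping) -> "HaplogroupTree":
        try:
            panel_records = doc["panel"]
            node_records = doc["nodes"]
        except (KeyError, TypeError) as exc:
            raise TreeConfigError(
                "tree config must be an object with 'panel' and 'nodes' arrays"
            ) from exc

        panel: list[PanelSnp] = []
        for record in panel_records:
            try:
                panel.append(
                    PanelSnp(
                        name=str(record["name"]),
                        position=int(record["position"]),
                        ancestral_allele=str(record["ancestral"]).upper(),
                        derived_allele=str(record["derived"]).upper(),
                        in_qc_blacklist=bool(record.get("qc_blacklist", False)),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise TreeConfigError(
                    f"malformed panel record {record!r}: {exc}"
                ) from exc

        nodes: dict[str, HaplogroupNode] = {}
        root: HaplogroupNode | None = None
        for record in node_records:
            try:
                name = str(record["name"])
                parent_name = record["parent"]
                lineage = str(record["lineage"])
                genotypes = tuple(
                    (int(p), str(a).upper()) for p, a in record["genotypes"]
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise TreeConfigError(
                    f"malformed node record {record!r}: {exc}"
                ) from exc
            if name in nodes:
                raise TreeConfigError(f"duplicate node name {name!r}")
            node = HaplogroupNode(
                name=name, required_genotypes=genotypes, lineage=lineage
            )
            if parent_name is None:
                if root is not None:
                    raise TreeConfigError(
                        f"second parentless node {name!r} (root is {root.name!r})"
                    )
                root = node
            else:
                parent = nodes.get(str(parent_name))
                if parent is None:
                    raise TreeConfigError(
                        f"node {name!r}: parent {parent_name!r} not defined "
                        "earlier in the config (parents must precede children)"
                    )
                node.parent = parent
                parent.children.append(node)
            nodes[name] = node
        if root is None:
            raise TreeConfigError("no root node (every node has a parent)")

        tree = cls(root, nodes, panel)

        expected = doc.get("haplogroup_count")
        if expected is not None and tree.n_haplogroups != int(expected):
            raise TreeValidationError(
                f"config declares {expected} haplogroups but defines "
                f"{tree.n_haplogroups} non-root nodes"
            )
        return tree

    def to_dict(self) -> dict:
        panel = [
            {
                "name": snp.name,
                "position": snp.position,
                "ancestral": snp.ancestral_allele,
                "derived": snp.derived_allele,
                "qc_blacklist": snp.in_qc_blacklist,
            }
            for snp in (self.panel[p] for p in sorted(self.panel))
        ]
        nodes = [
            {
                "name": node.name,
                "parent": node.parent.name if node.parent else None,
                "lineage": node.lineage,
                "genotypes": [[p, a] for p, a in node.required_genotypes],
            }
            for node in self.nodes.values()
        ]
        return {
            "haplogroup_count": self.n_haplogroups,
            "panel": panel,
            "nodes": nodes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1) + "\n", encoding="utf-8"
        )


def load_tree(config_path: str | Path) -> HaplogroupTree:
    """Load and validate a tree/panel JSON configuration file."""
    path = Path(config_path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise TreeConfigError(f"{path}: not valid JSON ({exc})") from exc
    return HaplogroupTree.from_dict(doc)


def default_tree() -> HaplogroupTree:
    """The packaged default reduced tree (46 haplogroups, 63-SNP panel)."""
    text = (
        resources.files("mitoclass.data")
        .joinpath(DEFAULT_TREE_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return HaplogroupTree.from_dict(json.loads(text))


def path_to_root(tree: HaplogroupTree, node_name: str) -> list[str]:
    """Functional alias for :meth:`HaplogroupTree.path_to_root`."""
    return tree.path_to_root(node_name)


def required_genotypes_cumulative(
    tree: HaplogroupTree, node_name: str
) -> list[tuple[int, str]]:
    """Functional alias for cumulative root->node requirements."""
    return tree.required_genotypes_cumulative(node_name)
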