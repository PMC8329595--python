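"""Presence/absence matrices and Dollo-parsimony gain/loss mapping.

A character (a peptide family or one of its groups) is assumed to arise
exactly once (Dollo assumption): the gain is placed at the most recent
common ancestor of the tips where the character was detected, and losses
are the maximal subtrees below the gain whose tips are all
``not_detected``. Under a single irreversible gain this placement is the
minimum-loss reconstruction. "not_detected" is deliberately distinct
from confirmed absence: transcriptome datasets can miss low-abundance
transcripts, so the sensitivity report flags such cells as possible
false negatives unless the dataset is a genome-derived proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import dendropy

PRESENT = "present"
NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class PresenceCell:
    state: str  # present | not_detected
    evidence: int = 0
    flag: str = ""


@dataclass
class PresenceMatrix:
    """taxa x character detection calls with per-cell evidence counts."""

    taxa: list[str]
    characters: list[str]
    cells: dict[tuple[str, str], PresenceCell]

    def state(self, taxon: str, character: str) -> str:
        return self.cells[(taxon, character)].state

    def presence_vector(self, character: str) -> dict[str, bool]:
        return {t: self.cells[(t, character)].state == PRESENT for t in self.taxa}

    def rows(self) -> list[dict]:
        out = []
        for t in self.taxa:
            row: dict = {"taxon": t}
            for ch in self.characters:
                cell = self.cells[(t, ch)]
                mark = "+" if cell.state == PRESENT else "n.d."
                if cell.flag:
                    mark += f" ({cell.flag})"
                row[ch] = mark
                row[f"{ch}_n"] = cell.evidence
            out.append(row)
        return out


@dataclass(frozen=True)
class GainLossMap:
    character: str
    gain_node: str | None  # label of the gain node (None when never present)
    loss_edges: tuple[str, ...]  # labels of child nodes of the loss edges
    n_independent_losses: int


def build_presence(classified: Iterable[Mapping],
                   manifest_taxa: Sequence[str],
                   tree: dendropy.Tree,
                   characters: Sequence[str] | None = None,
                   min_evidence: int = 1) -> PresenceMatrix:
    """Tabulate detection calls per searched taxon.

    ``classified`` rows need 'taxon' and 'character' keys (one row per
    curated candidate). Every searched taxon appears in the matrix even
    with zero hits (as not_detected); a candidate taxon missing from the
    tree is an error.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in manifest_taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa not in tree: {', '.join(sorted(missing))}")
    counts: dict[tuple[str, str], int] = {}
    chars_seen: list[str] = []
    for row in classified:
        t, ch = row["taxon"], row["character"]
        if t not in tips:
            raise ValueError(f"candidate taxon {t!r} not a tree tip")
        counts[(t, ch)] = counts.get((t, ch), 0) + 1
        if ch not in chars_seen:
            chars_seen.append(ch)
    characters = list(characters) if characters else chars_seen
    cells = {}
    for t in manifest_taxa:
        for ch in characters:
            n = counts.get((t, ch), 0)
            state = PRESENT if n >= min_evidence else NOT_DETECTED
            cells[(t, ch)] = PresenceCell(state, n)
    return PresenceMatrix(list(manifest_taxa), characters, cells)


def _tip_labels(node: dendropy.Node) -> list[str]:
    return [leaf.taxon.label for leaf in node.leaf_iter()]


def dollo_map(tree: dendropy.Tree, presence: Mapping[str, bool],
              character: str = "character") -> GainLossMap:
    """Single-gain / minimal-loss placement of a binary character.

    Tips not mentioned in ``presence`` are treated as outside the study
    (ignored for the gain, never assigned a loss of their own).
    """
    present_tips = [t for t, p in presence.items() if p]
    if not present_tips:
        return GainLossMap(character, None, (), 0)
    taxa = [tree.taxon_namespace.get_taxon(t) for t in present_tips]
    if any(tx is None for tx in taxa):
        bad = [t for t, tx in zip(present_tips, taxa) if tx is None]
        raise ValueError(f"present taxa not in tree: {', '.join(bad)}")
    gain = tree.mrca(taxa=taxa) if len(taxa) > 1 else \
        tree.find_node_with_taxon_label(present_tips[0])
    losses: list[str] = []

    def walk(node: dendropy.Node) -> bool:
        """Returns True when the clade below ``node`` contains any present
        (or unscored) tip; records a loss at each maximal all-absent clade."""
        if node.is_leaf():
            label = node.taxon.label
            return presence.get(label, True)
        child_alive = [(c, walk(c)) for c in node.child_nodes()]
        if any(alive for _, alive in child_alive):
            for child, alive in child_alive:
                if not alive:
                    losses.append(_node_label(child))
            return True
        return False

    scored_below = [l for l in _tip_labels(gain) if l in presence]
    if not walk(gain) and scored_below:
        # cannot happen: gain is the MRCA of present tips
        raise AssertionError("gain node contains no present tip")
    losses.sort()
    return GainLossMap(character, _node_label(gain), tuple(losses), len(losses))


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or "+".join(sorted(_tip_labels(node)))


def enumerate_loss_oracle(tree: dendropy.Tree, presence: Mapping[str, bool],
                          max_tips: int = 12) -> int:
    """Exhaustive minimal loss count under a single gain at the MRCA of
    present tips: tries edge subsets of increasing size until the absent
    tips are exactly the tips below the chosen loss edges. Independent of
    dollo_map's clade logic; small trees only."""
    present_tips = {t for t, p in presence.items() if p}
    if not present_tips:
        return 0
    if len(tree.leaf_nodes()) > max_tips:
        raise ValueError(f"oracle limited to {max_tips} tips")
    taxa = [tree.taxon_namespace.get_taxon(t) for t in present_tips]
    gain = tree.mrca(taxa=taxa) if len(taxa) > 1 else \
        tree.find_node_with_taxon_label(next(iter(present_tips)))
    absent = {l for l in _tip_labels(gain) if l in presence and l not in present_tips}
    if not absent:
        return 0
    # candidate loss edges: any edge below the gain whose clade consists
    # entirely of scored-absent tips (unscored tips are treated as alive,
    # matching the reconstruction's semantics)
    candidates = []
    for node in gain.preorder_iter():
        if node is gain:
            continue
        below = set(_tip_labels(node))
        if below and below <= absent:
            candidates.append(frozenset(below))
    for k in range(1, len(candidates) + 1):
        for combo in combinations(candidates, k):
            union: set[str] = set()
            total = 0
            for cl in combo:
                union |= cl
                total += len(cl)
            if total == len(union) and union == absent:  # disjoint exact cover
                return k
    raise AssertionError("no loss placement covers the absent tips")


def sensitivity_report(matrix: PresenceMatrix,
                       data_types: Mapping[str, str]) -> PresenceMatrix:
    """Flag not_detected cells of transcriptome-only taxa as possible
    false negatives; genome-backed (proteome) evidence leaves the call
    unflagged. ``data_types`` maps taxon -> 'transcriptome'/'proteome'
    (a taxon with any proteome dataset counts as genome-backed)."""
    cells = {}
    for key, cell in matrix.cells.items():
        taxon = key[0]
        if cell.state == NOT_DETECTED and data_types.get(taxon) == "transcriptome":
            cell = PresenceCell(cell.state, cell.evidence, "possible false negative")
        cells[key] = cell
    return PresenceMatrix(matrix.taxa, matrix.characters, cells)


def gain_loss_rows(maps: Iterable[GainLossMap]) -> list[dict]:
    rows = []
    for m in maps:
        rows.append({"character": m.character,
                     "gain_node": m.gain_node or "",
                     "n_independent_losses": m.n_independent_losses,
                     "loss_edges": ";".join(m.loss_edges)})
    return rows


def annotated_newick(tree: dendropy.Tree, gmap: GainLossMap) -> str:
    """The input tree with gain/loss comments attached to node labels."""
    clone = tree.clone(depth=1)
    losses = set(gmap.loss_edges)
    for node in clone.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else (node.label or "")
        marks = []
        if gmap.gain_node and label == gmap.gain_node:
            marks.append("gain")
        if label in losses or (node.is_leaf() and node.taxon.label in losses):
            marks.append(f"loss:{gmap.character}")
        if marks and not node.is_leaf():
            node.label = f"{label}[{'|'.join(marks)}]"
        elif marks:
            node.taxon.label = f"{label}[{'|'.join(marks)}]"
    return clone.as_string(schema="newick").strip()
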