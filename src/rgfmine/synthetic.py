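"""Ground-truthed synthetic transcriptomes/proteomes and tree scenarios.

The generator emulates the kind of data the mining pipeline is built
for: assembled transcripts carrying a short-peptide precursor ORF — a
hydrophobic N-terminal stretch, a variable linker with planted
basic-residue cleavage motifs, a 13/14-residue D-Y-anchored mature
peptide drawn from a group-specific position weight matrix, and a
group-dependent C-terminal extension — embedded on a random strand and
frame among decoy transcripts, plus per-taxon presence/absence produced
by irreversible loss events on a species tree.

Mature-peptide noise (``mutation_rate``) is applied per site to
positions 3-13 only: the D-Y anchor defines family membership under the
mining rule, so a peptide with a substituted anchor would not be a
family member at all rather than a divergent one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import dendropy
from Bio.Data import CodonTable

from .peptide import GROUP_CONSENSUS, MaturePeptide, max_anchor_conservation
from .phylo import GainLossMap
from .seqio import STANDARD_AA, SequenceRecord, read_newick, reverse_complement, write_fasta, write_tsv

#: residues used for unconstrained positions/regions: no D or Y (cannot
#: spawn spurious anchors), no R/K (cannot spawn spurious cleavage motifs),
#: no P/H/N (cannot inflate conservation scores).
NEUTRAL_POOL = "AEGILQSTVW"
HYDROPHOBIC_POOL = "LVIAFMWTS"

GROUPS = ("H", "R", "H-PP")
#: intended classification (group, subgroup) per generator group label
GROUP_TRUTH = {"H": ("H", "H-N"), "R": ("R", "none"), "H-PP": ("H", "H-PP")}


def group_pwm(group: str) -> list[dict[str, float]]:
    """The 13-column position weight matrix of a group: diagnostic
    positions carry their residues; free positions are uniform over the
    neutral pool."""
    free = {a: 1 / len(NEUTRAL_POOL) for a in NEUTRAL_POOL}
    cols: list[dict[str, float]] = [dict(free) for _ in range(13)]
    cols[0] = {"D": 1.0}
    cols[1] = {"Y": 1.0}
    cols[4] = {"P": 1.0}
    cols[8] = {"P": 1.0}
    cols[9] = {"P": 1.0}
    if group == "H":
        cols[7] = {"H": 1.0}
        cols[11] = {"N": 0.5, "H": 0.5}
        cols[12] = {"N": 1.0}
    elif group == "R":
        cols[6] = {"R": 0.5, "K": 0.5}
        cols[7] = {"R": 0.5, "K": 0.5}
        cols[11] = {"N": 1.0}
        cols[12] = {"N": 1.0}
    elif group == "H-PP":
        cols[7] = {"H": 1.0}
        cols[11] = {"P": 1.0}
        cols[12] = {"P": 1.0}
    else:
        raise ValueError(f"unknown group {group!r}")
    return cols


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int = 0
    n_precursors: int = 20
    n_decoys: int = 180
    group_mix: tuple[tuple[str, float], ...] = (("H", 0.5), ("R", 0.3), ("H-PP", 0.2))
    mutation_rate: float = 0.0  # per mature site, positions 3-13
    triple_p_prob: float = 0.0  # Group H draws: 14-mer triple-proline variant
    cleavage_count: int = 2
    nterm_len: tuple[int, int] = (15, 30)
    linker_len: tuple[int, int] = (30, 80)
    utr_len: tuple[int, int] = (20, 100)
    r_extension: tuple[int, int] = (9, 18)
    long_extension: tuple[int, int] = (21, 35)
    long_extension_prob: float = 0.5  # H-PP only
    paired_fraction: float = 0.0  # fraction of precursors emitted as H/R pairs
    detection_dropout: float = 0.0  # transcriptome taxa only
    loss_probability: float = 0.0  # per tree edge
    min_decoy_rejection: int = 5  # resample decoys reaching this conservation

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.group_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("group_mix proportions must sum to 1")
        for p in (self.mutation_rate, self.detection_dropout,
                  self.loss_probability, self.long_extension_prob,
                  self.paired_fraction, self.triple_p_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruthRecord:
    taxon: str
    transcript_id: str
    precursor: str
    mature: str
    group: str  # intended group (H | R)
    subgroup: str
    frame: int  # 0 for proteome records
    strand: str
    cleavage_positions: tuple[int, ...]  # 0-based precursor coords
    extension_length: int
    paired_with: str = ""


def _choice(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(pool[i] for i in rng.integers(0, len(pool), size=n))


def sample_mature(group: str, config: GeneratorConfig,
                  rng: np.random.Generator) -> MaturePeptide:
    """Draw a mature peptide from the group PWM, optionally insert the
    triple-proline extra residue, then apply per-site substitution noise
    to the non-anchor positions."""
    residues = []
    for col in group_pwm(group):
        aas = sorted(col)
        probs = np.array([col[a] for a in aas])
        residues.append(aas[int(rng.choice(len(aas), p=probs / probs.sum()))])
    if config.mutation_rate > 0:  # noise on non-anchor positions (3-13)
        for i in range(2, len(residues)):
            if rng.random() < config.mutation_rate:
                alternatives = [a for a in STANDARD_AA if a != residues[i]]
                residues[i] = alternatives[int(rng.integers(len(alternatives)))]
    variant = "canonical_13"
    if (group == "H" and rng.random() < config.triple_p_prob
            and residues[8] == "P" and residues[9] == "P"):
        residues.insert(10, "P")  # P at 9,10,11 of the resulting 14-mer
        variant = "triple_P_14"
    return MaturePeptide("".join(residues), 0, variant=variant)


def _linker(config: GeneratorConfig, rng: np.random.Generator,
            nterm_len: int) -> tuple[str, list[int]]:
    """Variable linker with exactly ``cleavage_count`` dibasic motifs,
    placed non-adjacently and only where the annotation scanner looks
    (precursor position > 20)."""
    length = int(rng.integers(*config.linker_len, endpoint=True))
    chars = list(_choice(rng, NEUTRAL_POOL, length))
    lo = max(0, 22 - nterm_len)  # keep motifs inside the scanned region
    hi = length - 6  # and clear of the query-context residues
    positions: list[int] = []
    attempts = 0
    while len(positions) < config.cleavage_count and attempts < 1000:
        attempts += 1
        p = int(rng.integers(lo, max(lo + 1, hi)))
        if all(abs(p - q) >= 3 for q in positions):
            positions.append(p)
    positions.sort()
    for p in positions:
        motif = ("KR", "RR", "RK", "KK")[int(rng.integers(4))]
        chars[p:p + 2] = list(motif)
    return "".join(chars), [nterm_len + p for p in positions]


def build_precursor(mature: MaturePeptide, group: str, config: GeneratorConfig,
                    rng: np.random.Generator) -> tuple[str, dict]:
    """Assemble N-terminal stretch + linker + mature + group-dependent
    extension; returns the protein and its ground-truth fields."""
    nterm = "M" + _choice(rng, HYDROPHOBIC_POOL,
                          int(rng.integers(*config.nterm_len, endpoint=True)) - 1)
    linker, cleavage_positions = _linker(config, rng, len(nterm))
    if group == "R":
        ext_len = int(rng.integers(*config.r_extension, endpoint=True))
    elif group == "H-PP" and rng.random() < config.long_extension_prob:
        ext_len = int(rng.integers(*config.long_extension, endpoint=True))
    else:
        ext_len = 0
    extension = _choice(rng, NEUTRAL_POOL, ext_len)
    protein = nterm + linker + mature.residues + extension
    truth = {
        "mature_start": len(nterm) + len(linker),
        "cleavage_positions": tuple(cleavage_positions),
        "extension_length": ext_len,
    }
    return protein, truth


# --- nucleotide embedding --------------------------------------------------

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for aa in _AA_TO_CODONS:
    _AA_TO_CODONS[aa].sort()
_STOP_CODONS = sorted(_CODON_TABLE.stop_codons)
_NT = "ACGT"


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice (no codon-bias model)."""
    return "".join(_AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
                   for aa in protein)


def embed_transcript(precursor: str, config: GeneratorConfig,
                     rng: np.random.Generator,
                     transcript_id: str = "tx") -> tuple[SequenceRecord, int, str]:
    """Place the reverse-translated precursor ORF (with an in-frame
    upstream stop and its own stop codon) between random UTRs, on a
    random strand. Returns (record, frame, strand) where ``frame`` is the
    reading frame of the emitted sequence containing the precursor."""
    cds = reverse_translate(precursor, rng)
    stop = _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
    utr5 = _choice(rng, _NT, int(rng.integers(*config.utr_len, endpoint=True)))
    utr5 += _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]  # in-frame stop before the ORF
    utr3 = _choice(rng, _NT, int(rng.integers(*config.utr_len, endpoint=True)))
    plus = utr5 + cds + stop + utr3
    frame = len(utr5) % 3 + 1
    if rng.random() < 0.5:
        seq, frame, strand = reverse_complement(plus), -frame, "-"
    else:
        seq, strand = plus, "+"
    return SequenceRecord(transcript_id, seq, "nucleotide"), frame, strand


def _decoy_record(config: GeneratorConfig, rng: np.random.Generator,
                  template: str | None, decoy_id: str,
                  data_type: str) -> SequenceRecord:
    """A decoy: either a shuffled real precursor or a length-matched
    random-codon ORF; resampled until no D-Y-anchored window anywhere
    (any of the six frames for transcripts) reaches the curation
    conservation threshold."""
    from .seqio import six_frame_translate
    for _ in range(200):
        if template is not None:
            chars = np.array(list(template[1:]))
            rng.shuffle(chars)
            protein = "M" + "".join(chars)
        else:
            length = int(rng.integers(60, 140))
            protein = "M" + _choice(rng, STANDARD_AA, length - 1)
        if data_type == "proteome":
            if max_anchor_conservation(protein) < config.min_decoy_rejection:
                return SequenceRecord(decoy_id, protein, "protein")
            continue
        rec, _, _ = embed_transcript(protein, config, rng, decoy_id)
        if all(max_anchor_conservation(f.residues) < config.min_decoy_rejection
               for f in six_frame_translate(rec)):
            return rec
    raise RuntimeError("could not sample an acceptable decoy")


@dataclass
class SyntheticDataset:
    """One taxon's emitted dataset plus its ground truth."""

    taxon: str
    data_type: str  # transcriptome | proteome
    records: list[SequenceRecord]
    truths: list[GroundTruthRecord]


def generate_taxon(taxon: str, config: GeneratorConfig, rng: np.random.Generator,
                   data_type: str = "transcriptome",
                   carries_family: bool = True) -> SyntheticDataset:
    """Generate one taxon's transcripts (or proteins): embedded precursors
    when the taxon carries the family (minus detection dropout for
    transcriptomes), plus decoys."""
    records: list[SequenceRecord] = []
    truths: list[GroundTruthRecord] = []
    templates: list[str] = []
    groups = [g for g, _ in config.group_mix]
    weights = np.array([w for _, w in config.group_mix])

    n_emit = config.n_precursors if carries_family else 0
    i = 0
    while i < n_emit:
        paired = config.paired_fraction > 0 and rng.random() < config.paired_fraction \
            and i + 1 < n_emit
        if paired:
            specs = [("H", f"{taxon}_pre{i:03d}"), ("R", f"{taxon}_pre{i + 1:03d}")]
        else:
            g = groups[int(rng.choice(len(groups), p=weights / weights.sum()))]
            specs = [(g, f"{taxon}_pre{i:03d}")]
        shared: tuple[str, list[int]] | None = None
        ids = [sid for _, sid in specs]
        for k, (g, tid) in enumerate(specs):
            mature = sample_mature(g, config, rng)
            if shared is None:
                protein, truth = build_precursor(mature, g, config, rng)
                if paired:
                    shared = (protein[:truth["mature_start"]], list(truth["cleavage_positions"]))
            else:  # paired partner: identical N-terminal region, own mature/extension
                upstream, cleav = shared
                ext_len = int(rng.integers(*config.r_extension, endpoint=True)) if g == "R" else 0
                protein = upstream + mature.residues + _choice(rng, NEUTRAL_POOL, ext_len)
                truth = {"mature_start": len(upstream),
                         "cleavage_positions": tuple(cleav), "extension_length": ext_len}
            templates.append(protein)
            dropped = (data_type == "transcriptome"
                       and rng.random() < config.detection_dropout)
            group, subgroup = GROUP_TRUTH[g]
            if data_type == "proteome":
                rec = SequenceRecord(tid, protein, "protein", taxon=taxon)
                frame, strand = 0, "."
            else:
                rec, frame, strand = embed_transcript(protein, config, rng, tid)
                rec = SequenceRecord(rec.id, rec.residues, "nucleotide", taxon=taxon)
            if not dropped:
                records.append(rec)
                truths.append(GroundTruthRecord(
                    taxon=taxon, transcript_id=tid, precursor=protein,
                    mature=mature.residues, group=group, subgroup=subgroup,
                    frame=frame, strand=strand,
                    cleavage_positions=truth["cleavage_positions"],
                    extension_length=truth["extension_length"],
                    paired_with=ids[1 - k] if paired else ""))
            i += 1

    for d in range(config.n_decoys):
        template = None
        if templates and rng.random() < 0.5:
            template = templates[int(rng.integers(len(templates)))]
        rec = _decoy_record(config, rng, template, f"{taxon}_dec{d:03d}", data_type)
        records.append(SequenceRecord(rec.id, rec.residues, rec.alphabet, taxon=taxon))
    return SyntheticDataset(taxon, data_type, records, truths)


def verify_truth(dataset: SyntheticDataset) -> None:
    """Independent re-translation check: every truth precursor must be
    recoverable verbatim from the emitted record."""
    by_id = {r.id: r for r in dataset.records}
    for t in dataset.truths:
        rec = by_id[t.transcript_id]
        if t.frame == 0:
            assert rec.residues == t.precursor, t.transcript_id
            continue
        from .seqio import six_frame_translate  # local to avoid cycle at import
        frames = {f.frame: f.residues for f in six_frame_translate(rec)}
        assert t.precursor in frames[t.frame], (
            f"{t.transcript_id}: precursor not in recorded frame {t.frame}")


# --- tree scenarios --------------------------------------------------------

@dataclass
class TreeSimulation:
    tree: dendropy.Tree
    datasets: dict[str, SyntheticDataset]
    presence: dict[str, bool]
    true_map: GainLossMap  # identifiable (canonical) form, see below
    event_edges: tuple[str, ...]  # raw simulated loss events
    data_types: dict[str, str]


def _canonical_true_map(tree: dendropy.Tree, state: Mapping[int, bool],
                        character: str) -> GainLossMap:
    """The identifiable form of the simulated history: the gain sits at
    the most recent common ancestor of surviving tips, and each loss is a
    maximal fully-lost clade below it. Sibling losses (or a loss stacked
    above further losses, or outside the surviving clade) cannot be told
    apart from tip data, so the truth is reported in this canonical form.
    Computed from the simulated node states, not from tip presence."""
    from .phylo import _node_label

    def tips_below(node):
        return list(node.leaf_iter())

    survivors = [l for l in tree.leaf_node_iter() if state[id(l)]]
    if not survivors:
        return GainLossMap(character, None, (), 0)
    gain = tree.seed_node
    while True:
        kids = [c for c in gain.child_nodes()
                if any(state[id(l)] for l in tips_below(c))]
        if len(kids) == 1 and not gain.is_leaf():
            gain = kids[0]
        else:
            break
    losses: list[str] = []

    def collect(node):
        for child in node.child_nodes():
            if not any(state[id(l)] for l in tips_below(child)):
                losses.append(_node_label(child))
            else:
                collect(child)

    collect(gain)
    return GainLossMap(character, _node_label(gain), tuple(sorted(losses)),
                       len(losses))


def simulate_family_on_tree(tree_source: str, config: GeneratorConfig,
                            data_types: Mapping[str, str] | None = None,
                            character: str = "family") -> TreeSimulation:
    """Evolve the family by Dollo dynamics (present at the root, lost
    irreversibly with per-edge probability) and emit one dataset per tip:
    embedded precursors where the family survives, decoys only where it
    was lost. The true gain/loss map is recorded in its identifiable
    canonical form; the raw event edges are kept alongside."""
    rng = np.random.default_rng(config.seed)
    tree = read_newick(tree_source)
    state: dict[int, bool] = {}
    event_edges: list[str] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state[id(node)] = True
            continue
        parent_present = state[id(node.parent_node)]
        present = parent_present
        if parent_present and rng.random() < config.loss_probability:
            present = False
            from .phylo import _node_label
            event_edges.append(_node_label(node))
        state[id(node)] = present
    presence = {leaf.taxon.label: state[id(leaf)] for leaf in tree.leaf_node_iter()}
    true_map = _canonical_true_map(tree, state, character)
    data_types = dict(data_types or {})
    datasets = {}
    for leaf in sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label):
        taxon = leaf.taxon.label
        dt = data_types.setdefault(taxon, "transcriptome")
        datasets[taxon] = generate_taxon(taxon, config, rng, dt,
                                         carries_family=presence[taxon])
    return TreeSimulation(tree, datasets, presence, true_map,
                          tuple(event_edges), data_types)


# --- emission --------------------------------------------------------------

def write_datasets(datasets: Mapping[str, SyntheticDataset], out_dir: str | Path,
                   header: str = "") -> Path:
    """Write per-taxon FASTA, the manifest TSV and the ground-truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_rows = [], []
    for taxon in sorted(datasets):
        ds = datasets[taxon]
        ext = "fna" if ds.data_type == "transcriptome" else "faa"
        fasta = out / f"{taxon}.{ext}"
        write_fasta(ds.records, fasta)
        manifest_rows.append({"file_path": str(fasta), "taxon": taxon,
                              "data_type": ds.data_type})
        for t in ds.truths:
            truth_rows.append({
                "taxon": t.taxon, "transcript_id": t.transcript_id,
                "group": t.group, "subgroup": t.subgroup,
                "mature": t.mature, "frame": t.frame, "strand": t.strand,
                "cleavage_positions": ";".join(str(p + 1) for p in t.cleavage_positions),
                "extension_length": t.extension_length,
                "paired_with": t.paired_with, "precursor": t.precursor})
    write_tsv(manifest_rows, out / "manifest.tsv", header or None)
    write_tsv(truth_rows, out / "truth.tsv", header or None)
    return out / "manifest.tsv"


def motif_seed_queries(n_samples: int = 2, seed: int = 12345,
                       context: str = "SKR") -> list[str]:
    """Built-in 16-residue seed queries: per group, the consensus mature
    prefixed by a generic dibasic context, plus deterministic PWM draws."""
    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(seed=seed)
    queries = []
    for g in GROUPS:
        queries.append(context + GROUP_CONSENSUS[g])
        for _ in range(n_samples):
            queries.append(context + sample_mature(g, cfg, rng).residues)
    out, seen = [], set()
    for q in queries:
        if q not in seen:
            seen.add(q)
            out.append(q)
    return out
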