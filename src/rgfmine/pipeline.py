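"""End-to-end orchestration: mine -> curate -> classify -> profile -> phylo.

One `RunConfig` (YAML-loadable) drives a reproducible run; every report
file carries the seed and a hash of the configuration in a comment
header, and identical config + seed yields identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import peptide, phylo, profile, search, seqio, synthetic

log = logging.getLogger("rgfmine")


@dataclass
class RunConfig:
    manifest: str
    tree: str | None = None
    query_fasta: str | None = None  # None -> built-in motif seed queries
    out_dir: str = "rgfmine_out"
    seed: int = 0
    min_conservation: int = 5
    score_slack: float = 0.8  # permissive raw-score gate; curation filters
    collapse_isoforms: bool = True
    second_round: bool = False  # re-search with round-1 matures as queries
    lineage_map: dict = field(default_factory=dict)  # taxon -> lineage label
    search_overrides: dict = field(default_factory=dict)
    min_evidence: int = 1
    assume_absent: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results go, not what is computed
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"seed={self.seed} config={self.config_hash()}"

    def search_params(self) -> search.SearchParams:
        kwargs = {"score_slack": self.score_slack}
        kwargs.update(self.search_overrides)
        return search.SearchParams(**kwargs)


def load_queries(config: RunConfig) -> list[seqio.SequenceRecord]:
    if config.query_fasta:
        return seqio.read_fasta(config.query_fasta, "protein")
    return [seqio.SequenceRecord(f"seed{i:02d}", q, "protein")
            for i, q in enumerate(synthetic.motif_seed_queries())]


def _frame_proteins(records: Sequence[seqio.SequenceRecord]) -> dict[tuple[str, int], str]:
    proteins: dict[tuple[str, int], str] = {}
    for rec in records:
        if rec.alphabet == "nucleotide":
            for fr in seqio.six_frame_translate(rec):
                proteins[(rec.id, fr.frame)] = fr.residues
        else:
            proteins[(rec.id, 0)] = rec.residues
    return proteins


def _mine_taxon(entry: seqio.ManifestEntry, queries, params, matrix,
                config: RunConfig) -> tuple[list[peptide.PrecursorCandidate], list[dict], int]:
    alphabet = "nucleotide" if entry.data_type == "transcriptome" else "protein"
    records = seqio.read_fasta(entry.file_path, alphabet, taxon=entry.taxon)
    results = search.search(queries, records, params, matrix)
    hsps = [h for hits in results.values() for h in hits]
    proteins = _frame_proteins(records)
    candidates, dropped = peptide.curate_hits(
        hsps, proteins, taxon=entry.taxon,
        min_conservation=config.min_conservation,
        collapse=config.collapse_isoforms)
    return candidates, dropped, len(records)


def candidate_row(cand: peptide.PrecursorCandidate, lineage: str | None) -> dict:
    cls = peptide.classify(cand.mature, lineage)
    cleav = peptide.annotate_cleavage(cand)
    ext_len, ext_flag = peptide.c_terminal_extension(cand)
    return {
        "taxon": cand.taxon, "source_id": cand.source_id, "frame": cand.frame,
        "precursor_start": cand.orf_start + 1, "precursor_end": cand.orf_end,
        "mature": cand.mature.residues,
        "mature_start": cand.mature.start + 1,
        "variant": cand.mature.variant,
        "group": cls.group, "subgroup": cls.subgroup,
        "conservation_score": cls.conservation_score,
        "twelfth_residue": cls.twelfth_residue,
        "cleavage_count": cleav.count,
        "extension_length": "" if ext_len is None else ext_len,
        "extension_flag": ext_flag,
        "paired_with": "",
        "completeness": cand.completeness,
        "raw_score": cand.best_score,
    }


def run_mine(config: RunConfig) -> pd.DataFrame:
    """Per-taxon search + curation + classification.

    Transcriptome datasets are searched in all six translated frames;
    proteome datasets in protein space. Returns the candidate table and
    writes hits.tsv / candidates.tsv / dropped.tsv under out_dir.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = seqio.read_manifest(config.manifest)
    queries = load_queries(config)
    params = config.search_params()
    matrix = search.load_matrix()

    rows, all_dropped, hit_rows = [], [], []
    per_taxon_cands: dict[str, list[peptide.PrecursorCandidate]] = {}
    for entry in manifest:
        candidates, dropped, n_rec = _mine_taxon(entry, queries, params, matrix, config)
        if config.second_round and candidates:
            extra = peptide.build_query_set(
                [(c.protein, c.mature.start, c.mature) for c in candidates
                 if c.mature.start >= 3 and c.mature.variant == "canonical_13"])
            if extra:
                round2 = queries + [seqio.SequenceRecord(f"r2_{i}", q, "protein")
                                    for i, q in enumerate(extra)]
                candidates, dropped, n_rec = _mine_taxon(entry, round2, params, matrix, config)
        log.info("%s: %d records, %d candidates, %d dropped",
                 entry.taxon, n_rec, len(candidates), len(dropped))
        per_taxon_cands.setdefault(entry.taxon, []).extend(candidates)
        all_dropped.extend({"taxon": entry.taxon, **d} for d in dropped)

    for taxon in sorted(per_taxon_cands):
        cands = per_taxon_cands[taxon]
        lineage = config.lineage_map.get(taxon)
        taxon_rows = [candidate_row(c, lineage) for c in cands]
        classifications = [peptide.classify(c.mature, lineage) for c in cands]
        for h_cand, r_cand in peptide.detect_paired(cands, classifications):
            for row in taxon_rows:
                if row["source_id"] == h_cand.source_id and row["frame"] == h_cand.frame:
                    row["paired_with"] = r_cand.source_id
                if row["source_id"] == r_cand.source_id and row["frame"] == r_cand.frame:
                    row["paired_with"] = h_cand.source_id
        rows.extend(taxon_rows)

    table = pd.DataFrame(rows)
    header = config.header()
    seqio.write_tsv(rows, out / "candidates.tsv", header)
    seqio.write_tsv(all_dropped, out / "dropped.tsv", header)
    return table


def run_profile(config: RunConfig, table: pd.DataFrame,
                partition_by: str = "group") -> dict[str, profile.LogoMatrix]:
    """One logo per partition (default: per classified group)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logos = {}
    if table.empty:
        return logos
    work = table[table["group"] != "unassigned"]
    if partition_by == "lineage" and config.lineage_map:
        work = work.assign(partition=work["taxon"].map(config.lineage_map).fillna("other"))
    else:
        work = work.assign(partition=work[partition_by])
    for name, part in sorted(work.groupby("partition")):
        matures = [peptide.MaturePeptide(r.mature, 0, variant=r.variant)
                   for r in part.itertuples()]
        aln = profile.anchor_align(matures, partition=str(name))
        lm = profile.logo(aln)
        logos[str(name)] = lm
        seqio.write_tsv(profile.logo_rows(lm), out / f"logo_{name}.tsv", config.header())
    return logos


FAMILY_CHARACTER = "family"


def run_phylo(config: RunConfig, table: pd.DataFrame):
    """Presence matrix + Dollo gain/loss maps for the family and each
    group-level character."""
    if not config.tree:
        log.warning("no tree configured; phylo stage skipped")
        return None, []
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = seqio.read_newick(config.tree)
    manifest = seqio.read_manifest(config.manifest)
    taxa = sorted({e.taxon for e in manifest})
    classified = []
    for r in (table.itertuples() if not table.empty else ()):
        classified.append({"taxon": r.taxon, "character": FAMILY_CHARACTER})
        if r.group != "unassigned":
            classified.append({"taxon": r.taxon, "character": f"Group_{r.group}"})
    characters = [FAMILY_CHARACTER] + sorted(
        {c["character"] for c in classified} - {FAMILY_CHARACTER})
    matrix = phylo.build_presence(classified, taxa, tree, characters,
                                  min_evidence=config.min_evidence)
    data_types: dict[str, str] = {}
    for e in manifest:  # genome-backed evidence wins over transcriptome
        if data_types.get(e.taxon) != "proteome":
            data_types[e.taxon] = e.data_type
    matrix = phylo.sensitivity_report(matrix, data_types)
    maps = [phylo.dollo_map(tree, matrix.presence_vector(ch), ch)
            for ch in matrix.characters]
    header = config.header()
    seqio.write_tsv(matrix.rows(), out / "presence.tsv", header)
    seqio.write_tsv(phylo.gain_loss_rows(maps), out / "gain_loss.tsv", header)
    with open(out / "gain_loss.nwk", "w") as fh:
        for m in maps:
            if m.gain_node:
                fh.write(f"# {header} character={m.character}\n")
                fh.write(phylo.annotated_newick(tree, m) + "\n")
    return matrix, maps


def run_all(config: RunConfig) -> pd.DataFrame:
    """Full pipeline; also writes a small markdown summary."""
    table = run_mine(config)
    logos = run_profile(config, table)
    matrix, maps = run_phylo(config, table) if config.tree else (None, [])
    out = Path(config.out_dir)
    with open(out / "summary.md", "w") as fh:
        fh.write(f"# rgfmine run ({config.header()})\n\n")
        fh.write(f"- candidates: {len(table)}\n")
        if not table.empty:
            counts = table.groupby(["group", "subgroup"]).size()
            for (g, s), n in counts.items():
                fh.write(f"- group {g} / {s}: {n}\n")
        for name, lm in sorted(logos.items()):
            fh.write(f"- logo partition {name}: n={lm.n}\n")
        for m in maps:
            fh.write(f"- {m.character}: gain at {m.gain_node}, "
                     f"{m.n_independent_losses} independent loss(es)\n")
    return table
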