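"""Gap-free anchored alignment of mature peptides, position frequency
matrices, consensus calls and sequence-logo data.

Because every mature peptide is anchored at its D-Y start and is 13
(or 14, triple-proline variant) residues long, a full multiple-alignment
step is unnecessary: peptides are stacked with column 1 = D, and the
extra proline of 14-mers is placed in a flagged insertion column.

Logo information content follows the Shannon/Schneider convention used
by WebLogo: R_i = log2(20) - H_i (- e_n with the small-sample
correction, e_n = 19 / (2 ln2 n)), letter height = frequency x R_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import STANDARD_AA
from .peptide import MaturePeptide

_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}
N_ALPHABET = 20
MAX_BITS = math.log2(N_ALPHABET)


@dataclass(frozen=True)
class AnchoredAlignment:
    """Mature peptides aligned on the D-Y anchor.

    ``columns`` holds the residues of each of the 13 canonical columns;
    ``insertion`` holds the flagged insertion column (the extra P of
    triple-proline 14-mers), placed between canonical columns
    ``insertion_after`` and the next one.
    """

    peptides: tuple[MaturePeptide, ...]
    partition: str = ""
    insertion_after: int = 10  # 1-based canonical column the insertion follows

    def __post_init__(self) -> None:
        if not self.peptides:
            raise ValueError("anchored alignment needs at least one peptide")
        for p in self.peptides:
            if p.residues[:2] != "DY"[: len(p.residues)]:
                raise ValueError(f"peptide {p.residues!r} violates the D-Y anchor")

    @property
    def n(self) -> int:
        return len(self.peptides)

    def column(self, k: int) -> list[str]:
        """Residues of canonical column k (1-based, 1..13); partial
        peptides simply do not contribute to columns past their end."""
        out = []
        for p in self.peptides:
            c = p.collapsed
            if k <= len(c):
                out.append(c[k - 1])
        return out

    def insertion_column(self) -> list[str]:
        """Residues contributed to the insertion column (14-mers only)."""
        return [p.residues[10] for p in self.peptides if p.variant == "triple_P_14"]

    @property
    def has_insertion(self) -> bool:
        return any(p.variant == "triple_P_14" for p in self.peptides)


def anchor_align(matures: Sequence[MaturePeptide], partition: str = "",
                 insertion_after: int = 10) -> AnchoredAlignment:
    """Stack anchored mature peptides into a gap-free alignment."""
    return AnchoredAlignment(tuple(matures), partition, insertion_after)


@dataclass(frozen=True)
class LogoColumn:
    index: int  # 1-based canonical column, 0 for the insertion column
    n: int
    frequencies: dict[str, float]
    information: float  # R_i in bits

    def heights(self) -> dict[str, float]:
        return {a: f * self.information for a, f in self.frequencies.items() if f > 0}


@dataclass(frozen=True)
class LogoMatrix:
    columns: tuple[LogoColumn, ...]
    n: int
    partition: str = ""


def _column_logo(residues: Sequence[str], index: int, pseudocount: float,
                 small_sample_correction: bool) -> LogoColumn:
    counts = np.full(N_ALPHABET, pseudocount, dtype=float)
    n = 0
    for r in residues:
        i = _AA_INDEX.get(r)
        if i is not None:  # gaps, X and * are excluded from the counts
            counts[i] += 1
            n += 1
    total = counts.sum()
    if total == 0 or n == 0:
        freqs = np.zeros(N_ALPHABET)
        info = 0.0
    else:
        freqs = counts / total
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info = MAX_BITS - entropy
        if small_sample_correction:
            info -= (N_ALPHABET - 1) / (2 * math.log(2) * n)
        info = max(info, 0.0)
    return LogoColumn(index=index, n=n,
                      frequencies={a: float(freqs[i]) for a, i in _AA_INDEX.items()},
                      information=info)


def logo(alignment: AnchoredAlignment, pseudocount: float = 0.0,
         small_sample_correction: bool = False) -> LogoMatrix:
    """Per-column residue frequencies and information content (bits)."""
    cols = [_column_logo(alignment.column(k), k, pseudocount, small_sample_correction)
            for k in range(1, 14)]
    if alignment.has_insertion:
        ins = _column_logo(alignment.insertion_column(), 0, pseudocount,
                           small_sample_correction)
        cols.insert(alignment.insertion_after, ins)
    return LogoMatrix(tuple(cols), alignment.n, alignment.partition)


def consensus(logo_matrix: LogoMatrix, majority_threshold: float = 0.5,
              max_set: int = 3) -> str:
    """Per-column consensus: the residue whose frequency reaches the
    threshold, else the smallest residue set (by descending frequency)
    that covers it, rendered like 'R/K'; 'x' when more than ``max_set``
    residues would be needed. The insertion column is bracketed."""
    parts = []
    for col in logo_matrix.columns:
        ranked = sorted(col.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        cum, chosen = 0.0, []
        for a, f in ranked:
            if f <= 0:
                break
            chosen.append(a)
            cum += f
            if cum >= majority_threshold:
                break
        call = "/".join(chosen) if chosen and cum >= majority_threshold and len(chosen) <= max_set else "x"
        parts.append(f"[{call}]" if col.index == 0 else call)
    return " ".join(parts)


def logo_rows(logo_matrix: LogoMatrix) -> list[dict]:
    """Flatten a LogoMatrix to TSV-ready rows (column, residue, freq,
    height, information)."""
    rows = []
    for col in logo_matrix.columns:
        label = "ins" if col.index == 0 else str(col.index)
        for a in STANDARD_AA:
            f = col.frequencies[a]
            if f > 0:
                rows.append({"column": label, "residue": a,
                             "frequency": round(f, 6),
                             "height": round(f * col.information, 6),
                             "information": round(col.information, 6)})
    return rows


def plot_logo(logo_matrix: LogoMatrix, path: str, title: str = "") -> None:
    """Render a simple stacked-letter sequence logo to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    fp = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(logo_matrix.columns)), 3))
    for x, col in enumerate(logo_matrix.columns):
        y = 0.0
        for a, h in sorted(col.heights().items(), key=lambda kv: kv[1]):
            if h <= 0:
                continue
            tp = TextPath((0, 0), a, size=1, prop=fp)
            bb = tp.get_extents()
            tr = (Affine2D().translate(-bb.x0, -bb.y0)
                  .scale(0.9 / bb.width, h / bb.height).translate(x + 0.05, y))
            ax.add_patch(PathPatch(tr.transform_path(tp), facecolor="#2c5f8a",
                                   edgecolor="none"))
            y += h
    labels = ["ins" if c.index == 0 else str(c.index) for c in logo_matrix.columns]
    ax.set_xticks([i + 0.5 for i in range(len(labels))], labels)
    ax.set_xlim(0, len(logo_matrix.columns))
    ax.set_ylim(0, MAX_BITS)
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
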