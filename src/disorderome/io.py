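"""Readers and writers for every external representation the pipeline touches.

Formats covered: FASTA (sequences), aligned FASTA / ClustalW (MSAs), TSV
per-residue score tables (the common dialect onto which MFDp- or PONDR-style
predictor output is mapped), the classic PSI-BLAST ASCII PSSM whose second
block of 20 integer columns carries the Weighted Observed Percentages (WOP),
TSV function-labelled segment libraries (DisProt-style), and TSV interaction
edge lists.  Each reader is total on its writer's output.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .core import GAP, FormatError, ProteinRecord, ScoreTrack

#: Amino-acid column order of the PSI-BLAST ASCII PSSM.
PSIBLAST_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: The controlled vocabulary of disordered-segment functions (the 19 labels
#: observed in curated disordered-segment annotations) plus a catch-all.
FUNCTION_LABELS = (
    "Protein-protein binding",
    "Substrate/ligand binding",
    "Protein-DNA binding",
    "Flexible linkers/spacers",
    "Phosphorylation",
    "Intra-protein interaction",
    "Protein-lipid interaction",
    "Metal binding",
    "Nuclear localization",
    "Polymerization",
    "Electron transfer",
    "Entropic spring",
    "Transactivation",
    "Apoptosis Regulation",
    "Cofactor/heme binding",
    "Glycosylation",
    "Protein-tRNA binding",
    "Autoregulatory",
    "Entropic bristle",
)
OTHER_LABEL = "other"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records; sequences uppercased, trailing '*' stripped.

    Raises :class:`FormatError` on an empty file or duplicate ids.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Per-residue score tables
# ---------------------------------------------------------------------------

def read_score_table(path, *, dialect: str = "disorder", sequences=None) -> list[ScoreTrack]:
    """Read a TSV of per-residue scores (protein_id, position, residue, score).

    Positions must run contiguously 1..L within each protein.  In the
    ``disorder`` dialect scores must lie in [0, 1]; the ``free`` dialect
    only requires finite values.  When ``sequences`` (mapping id -> str) is
    given, the residue column is cross-checked against it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    required = {"protein_id", "position", "residue", "score"}
    if missing := required - set(df.columns):
        raise FormatError(f"score table {path} lacks columns {sorted(missing)}")
    tracks = []
    for pid, grp in df.groupby("protein_id", sort=False):
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise FormatError(f"positions for {pid!r} are not contiguous 1..L")
        scores = grp["score"].to_numpy(dtype=float)
        if dialect == "disorder" and ((scores < 0) | (scores > 1)).any():
            raise FormatError(f"disorder scores for {pid!r} outside [0, 1]")
        if not np.isfinite(scores).all():
            raise FormatError(f"non-finite score for {pid!r}")
        if sequences is not None and pid in sequences:
            expected = sequences[pid]
            observed = "".join(grp["residue"])
            if observed != expected:
                raise FormatError(f"residue column for {pid!r} disagrees with sequence")
        tracks.append(ScoreTrack(pid, scores))
    if not tracks:
        raise FormatError(f"empty score table {path}")
    return tracks


def write_score_table(path, tracks, sequences=None) -> None:
    rows = []
    for track in tracks:
        seq = sequences.get(track.protein_id) if sequences else None
        for i, score in enumerate(track.values):
            residue = seq[i] if seq else "X"
            rows.append((track.protein_id, i + 1, residue, score))
    pd.DataFrame(rows, columns=["protein_id", "position", "residue", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Multiple sequence alignments
# ---------------------------------------------------------------------------

def read_alignment(path) -> list[ProteinRecord]:
    """Read an MSA in aligned FASTA or ClustalW format (auto-detected).

    Gap characters are retained; each row's ungapped sequence is recoverable
    via :attr:`ProteinRecord.ungapped`.  Ragged alignments are rejected.
    """
    text = Path(path).read_text()
    fmt = "fasta" if text.lstrip().startswith(">") else "clustal"
    try:
        if fmt == "fasta":
            records = [
                ProteinRecord(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(_io.StringIO(text), "fasta")
            ]
        else:
            msa = AlignIO.read(_io.StringIO(text), "clustal")
            records = [ProteinRecord(rec.id, str(rec.seq).upper()) for rec in msa]
    except ValueError as exc:
        raise FormatError(f"cannot parse alignment {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no alignment rows in {path}")
    lengths = {len(rec) for rec in records}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment in {path}: row lengths {sorted(lengths)}")
    return records


def write_alignment(path, records, *, fmt: str = "fasta") -> None:
    if fmt == "fasta":
        write_fasta(path, records)
        return
    if fmt != "clustal":
        raise ValueError(f"unknown alignment format {fmt!r}")
    width = max(len(rec.id) for rec in records) + 3
    length = len(records[0].sequence)
    with open(path, "w") as fh:
        fh.write("CLUSTAL W multiple sequence alignment\n\n")
        for block in range(0, length, 60):
            for rec in records:
                fh.write(rec.id.ljust(width) + rec.sequence[block : block + 60] + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM (WOP block)
# ---------------------------------------------------------------------------

@dataclass
class WopProfile:
    """Per-residue Weighted Observed Percentages for one protein.

    ``wop`` is an (L, 20) integer array in PSI-BLAST column order
    (:data:`PSIBLAST_AA_ORDER`).  Rows summing to zero occur in genuine
    PSI-BLAST output (residues with no weighted observations) and are kept
    but flagged via :meth:`zero_rows`.
    """

    protein_id: str
    residues: str
    wop: np.ndarray

    def __post_init__(self) -> None:
        self.wop = np.asarray(self.wop, dtype=float)
        if self.wop.shape != (len(self.residues), 20):
            raise ValueError("WOP matrix must be (L, 20)")

    def __len__(self) -> int:
        return len(self.residues)

    def zero_rows(self) -> np.ndarray:
        return self.wop.sum(axis=1) == 0

    def probabilities(self) -> np.ndarray:
        """Row-normalised distributions; zero rows become NaN rows."""
        sums = self.wop.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.wop / sums
        p[np.squeeze(sums, axis=1) == 0] = np.nan
        return p


def read_wop_pssm(path, *, protein_id: str | None = None) -> WopProfile:
    """Parse the WOP block (columns 23-42) of a PSI-BLAST ASCII PSSM."""
    residues = []
    rows = []
    for line in Path(path).read_text().splitlines():
        tokens = line.split()
        if len(tokens) < 42 or not tokens[0].isdigit():
            continue  # headers, footer statistics, blank lines
        if len(tokens[1]) != 1:
            raise FormatError(f"malformed PSSM row in {path}: {line!r}")
        try:
            wop = [int(t) for t in tokens[22:42]]
        except ValueError as exc:
            raise FormatError(f"non-integer WOP value in {path}: {line!r}") from exc
        residues.append(tokens[1])
        rows.append(wop)
    if not rows:
        raise FormatError(f"no PSSM rows found in {path}")
    return WopProfile(protein_id or Path(path).stem, "".join(residues), np.array(rows))


def write_wop_pssm(path, profile: WopProfile) -> None:
    header = " ".join(PSIBLAST_AA_ORDER)
    with open(path, "w") as fh:
        fh.write(
            "\nLast position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write(" " * 12 + header + "   " + header + "\n")
        for i, (residue, row) in enumerate(zip(profile.residues, profile.wop), start=1):
            logodds = " ".join("0".rjust(3) for _ in range(20))  # placeholder block
            wop = " ".join(str(int(v)).rjust(4) for v in row)
            fh.write(f"{i:5d} {residue}  {logodds}  {wop}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# Annotated segment library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryEntry:
    entry_id: str
    sequence: str
    function: str


def read_segment_library(path) -> list[LibraryEntry]:
    """Read a TSV segment library (entry_id, sequence, function).

    Unknown function labels raise a warning and are mapped to ``other``;
    empty sequences are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if missing := {"entry_id", "sequence", "function"} - set(df.columns):
        raise FormatError(f"segment library {path} lacks columns {sorted(missing)}")
    known = set(FUNCTION_LABELS) | {OTHER_LABEL}
    entries = []
    for row in df.itertuples(index=False):
        if not row.sequence:
            raise FormatError(f"empty sequence for library entry {row.entry_id!r}")
        function = row.function
        if function not in known:
            warnings.warn(f"unknown function label {function!r}; mapped to {OTHER_LABEL!r}")
            function = OTHER_LABEL
        entries.append(LibraryEntry(row.entry_id, row.sequence.upper(), function))
    return entries


def write_segment_library(path, entries) -> None:
    pd.DataFrame(
        [(e.entry_id, e.sequence, e.function) for e in entries],
        columns=["entry_id", "sequence", "function"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interaction edge list
# ---------------------------------------------------------------------------

def read_edge_list(path) -> nx.Graph:
    """Read TSV protein pairs into an undirected simple graph.

    Duplicate edges collapse; self-loops are dropped with a warning.
    """
    graph = nx.Graph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two tab-separated ids")
        a, b = (p.strip() for p in parts)
        if a == b:
            warnings.warn(f"self-loop on {a!r} dropped")
            graph.add_node(a)
            continue
        graph.add_edge(a, b)
    return graph


def write_edge_list(path, graph: nx.Graph) -> None:
    with open(path, "w") as fh:
        for a, b in graph.edges():
            fh.write(f"{a}\t{b}\n")
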