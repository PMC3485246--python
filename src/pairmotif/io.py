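"""FASTA and tab-separated report formats.

FASTA parsing/writing is delegated to Biopython; records are uppercased
on read and validated to be nucleotide-dominant.  Two TSV formats are
defined (both with a header line):

ground-truth manifest (written by the simulator, read by evaluation)
    columns: sequence_id, position (0-based window start), instance,
    mutations.

motif report (written by search/score)
    columns: motif, n_sequences, max_distance, consensus_score,
    relative_entropy, then one ``position:distance`` field per sequence.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import EncodedLmer, PMSParams, SequenceRecord, decode_lmer
from .scoring import (
    InstanceAlignment,
    consensus_score,
    dataset_base_frequencies,
    extract_instances,
    relative_entropy,
)
from .simulate import Implant, PlantedDataset

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_manifest",
    "read_manifest",
    "write_motif_report",
    "read_motif_strings",
]

MANIFEST_COLUMNS = ("sequence_id", "position", "instance", "mutations")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an ordered list of DNA records, uppercased.

    Rejects empty files, records with empty sequences, and files whose
    content is not predominantly A/C/G/T (>10% other characters),
    which usually indicates a non-DNA or malformed input.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise ValueError(f"record {rec.id!r} in {path} has no sequence")
        records.append(SequenceRecord(identifier=rec.id, residues=residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    total = sum(len(r) for r in records)
    acgt = sum(r.residues.count(b) for r in records for b in "ACGT")
    if acgt < 0.9 * total:
        raise ValueError(
            f"{path} does not look like DNA: only {acgt}/{total} characters "
            "are A/C/G/T"
        )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records in FASTA, 60 columns per line."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.identifier, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def write_manifest(dataset: PlantedDataset, path: str | Path) -> None:
    """Write the planted ground truth as a TSV manifest."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for rec, imp in zip(dataset.sequences, dataset.implants):
            writer.writerow(
                [rec.identifier, imp.position, imp.instance, imp.mutations]
            )


def read_manifest(path: str | Path) -> dict[str, Implant]:
    """Read a ground-truth manifest keyed by sequence identifier."""
    implants: dict[str, Implant] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != MANIFEST_COLUMNS:
            raise ValueError(
                f"{path} is not a manifest: expected header "
                f"{list(MANIFEST_COLUMNS)}, got {header}"
            )
        for row in reader:
            if not row:
                continue
            seq_id, position, instance, mutations = row
            implants[seq_id] = Implant(
                position=int(position),
                instance=instance,
                mutations=int(mutations),
            )
    if not implants:
        raise ValueError(f"manifest {path} contains no rows")
    return implants


def _report_row(
    alignment: InstanceAlignment,
    background,
) -> list:
    positions = [f"{pos}:{dist}" for pos, _, dist in alignment.instances]
    return [
        decode_lmer(alignment.motif),
        alignment.n_sequences,
        max(dist for _, _, dist in alignment.instances),
        consensus_score(alignment),
        f"{relative_entropy(alignment, background):.4f}",
        *positions,
    ]


def write_motif_report(
    motifs: Iterable[EncodedLmer],
    sequences: Sequence[SequenceRecord],
    params: PMSParams,
    path: str | Path,
    uniform_background: bool = False,
    rank_by: str | None = None,
) -> None:
    """Write the ranked motif report TSV.

    One row per motif with its objective-function scores and per-sequence
    best occurrences; ``rank_by`` ("consensus" or "entropy") sorts rows
    by that score descending (ties broken lexicographically by motif),
    otherwise rows are in lexicographic motif order.
    """
    background = (
        None if uniform_background else dataset_base_frequencies(sequences)
    )
    alignments = [extract_instances(m, sequences, params) for m in motifs]
    rows = [_report_row(a, background) for a in alignments]
    if rank_by == "consensus":
        rows.sort(key=lambda r: (-r[3], r[0]))
    elif rank_by == "entropy":
        rows.sort(key=lambda r: (-float(r[4]), r[0]))
    elif rank_by is not None:
        raise ValueError(f"unknown ranking objective {rank_by!r}")
    header = [
        "motif",
        "n_sequences",
        "max_distance",
        "consensus_score",
        "relative_entropy",
        *[s.identifier for s in sequences],
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def read_motif_strings(path: str | Path) -> list[str]:
    """Read motif strings from a motif report TSV or a plain list (one
    motif per line)."""
    motifs = []
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path} is empty")
        fields = first.rstrip("\n").split("\t")
        if fields[0] != "motif":  # plain list, first line is a motif
            motifs.append(fields[0].strip())
        for line in fh:
            token = line.rstrip("\n").split("\t")[0].strip()
            if token:
                motifs.append(token)
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs
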