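"""Readers and writers for the standard formats.

FASTA and GenBank go through Biopython; Vienna dot-bracket and CT
(connectivity table) files are plain-text formats written directly.
All writers are deterministic: no timestamps inside data files (the
GenBank date annotation is pinned), so identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .constructs import Construct, Feature
from .errors import FormatError
from .folding.structure import SecondaryStructure, dotbracket_to_pairs

_GENBANK_DATE = "01-JAN-2000"  # pinned: writers must be byte-stable


# -- FASTA --------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) records; multi-record files keep input order."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")  # 60-column wrapping


# -- GenBank ------------------------------------------------------------


def write_genbank(construct: Construct, path: str | Path) -> None:
    """One misc_feature per part; internal 0-based half-open coordinates
    become GenBank 1-based inclusive on write (Biopython handles the
    conversion from FeatureLocation)."""
    record = SeqRecord(
        Seq(construct.sequence),
        id=construct.name[:16].replace(" ", "_").replace(":", "_"),
        name=construct.name[:16].replace(" ", "_").replace(":", "_"),
        description=f"{construct.topology} cassette",
        annotations={
            "molecule_type": "RNA" if construct.is_rna else "DNA",
            "date": _GENBANK_DATE,
            "topology": "circular" if construct.topology == "circular_rna"
            else "linear",
        },
    )
    for f in construct.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end),
                type="misc_feature",
                qualifiers={"label": [f.part], "note": [f.role]},
            )
        )
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "genbank")


def read_genbank(path: str | Path) -> Construct:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"no GenBank record in {path}") from None
    topology = "circular_rna" if record.annotations.get("topology") == "circular" \
        else "linear_gRNA"
    feats = []
    for f in sorted(record.features, key=lambda f: int(f.location.start)):
        if f.type != "misc_feature":
            continue
        feats.append(
            Feature(
                part=f.qualifiers.get("label", ["?"])[0],
                role=f.qualifiers.get("note", ["?"])[0],
                start=int(f.location.start),
                end=int(f.location.end),
            )
        )
    seq = str(record.seq).upper()
    is_rna = "U" in seq
    return Construct(
        name=record.name,
        topology=topology,
        sequence=seq.replace("U", "T") if is_rna else seq,
        features=tuple(feats),
        is_rna=False,
    ) if not is_rna else Construct(
        name=record.name, topology=topology, sequence=seq,
        features=tuple(feats), is_rna=True,
    )


# -- Vienna dot-bracket and CT ------------------------------------------


def write_dotbracket(structure: SecondaryStructure, path: str | Path,
                     name: str = "structure") -> None:
    """Vienna format: ``>name`` / sequence / dot-bracket (energy)."""
    text = (
        f">{name}\n{structure.sequence}\n"
        f"{structure.dotbracket} ({structure.dG:.2f})\n"
    )
    Path(path).write_text(text)


def read_dotbracket(path: str | Path) -> SecondaryStructure:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    lines = [l.rstrip("\n") for l in path.read_text().splitlines() if l.strip()]
    if len(lines) < 3 or not lines[0].startswith(">"):
        raise FormatError(f"{path}: expected >name / sequence / structure lines")
    seq = lines[1].strip().upper()
    rest = lines[2].strip()
    if " " in rest:
        db, _, tail = rest.partition(" ")
        try:
            energy = float(tail.strip().strip("()"))
        except ValueError:
            raise FormatError(f"{path}:3: cannot parse energy from {tail!r}") from None
    else:
        db, energy = rest, 0.0
    if len(db) != len(seq):
        raise FormatError(f"{path}:3: structure length != sequence length")
    try:
        dotbracket_to_pairs(db)
    except Exception as e:
        raise FormatError(f"{path}:3: {e}") from None
    return SecondaryStructure(sequence=seq, dotbracket=db, dG=energy,
                              engine_id="file")


def write_ct(structure: SecondaryStructure, path: str | Path,
             name: str = "structure") -> None:
    """Connectivity table: header then one line per nucleotide with its
    1-based pairing partner (0 = unpaired)."""
    n = len(structure.sequence)
    lines = [f"{n}\t{name}\tdG={structure.dG:.2f}"]
    for i in range(n):
        partner = structure.pair_table[i]
        lines.append(
            f"{i + 1}\t{structure.sequence[i]}\t{i}\t"
            f"{(i + 2) if i + 1 < n else 0}\t{partner + 1}\t{i + 1}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path: str | Path) -> SecondaryStructure:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (IndexError, ValueError):
        raise FormatError(f"{path}:1: cannot parse length") from None
    dG = 0.0
    for tok in head[1:]:
        if tok.startswith("dG="):
            dG = float(tok[3:])
    seq = []
    pairs = []
    for lineno, line in enumerate(lines[1 : n + 1], start=2):
        cols = line.split()
        if len(cols) < 6:
            raise FormatError(f"{path}:{lineno}: short CT line")
        idx = int(cols[0]) - 1
        seq.append(cols[1])
        partner = int(cols[4]) - 1
        if partner > idx:
            pairs.append((idx, partner))
    if len(seq) != n:
        raise FormatError(f"{path}: expected {n} nucleotide lines, got {len(seq)}")
    from .folding.structure import pairs_to_dotbracket

    db = pairs_to_dotbracket(pairs, n)
    return SecondaryStructure(sequence="".join(seq).upper(), dotbracket=db,
                              dG=dG, engine_id="file")


# -- tables and manifests ------------------------------------------------


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as e:
        raise FormatError(f"cannot parse TSV {path}: {e}") from None


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(manifest: dict, path: str | Path,
                   inputs: dict[str, str | Path] | None = None) -> None:
    """Run manifest: provenance JSON (the only place timestamps appear)."""
    out = dict(manifest)
    out["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    if inputs:
        out["input_digests"] = {
            k: file_digest(v) for k, v in sorted(inputs.items())
        }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
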