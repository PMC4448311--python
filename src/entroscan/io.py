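"""Format readers/writers and run configuration.

FASTA goes through Biopython; dot-bracket files are paired-line records
(header, sequence, structure); tables are tab-separated with '.' decimal
and a fixed column order so diffs stay meaningful.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .grammar import SecondaryStructure, normalize_sequence


def read_fasta(path: str | Path, dna_ok: bool = False, strict: bool = True) -> list[tuple[str, str]]:
    """Multi-record FASTA -> ordered (id, upper-cased sequence) pairs.

    ``dna_ok=True`` maps T→U (genome inputs); otherwise a T is an error,
    as is any character outside the four bases when ``strict``.
    Duplicate ids and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not dna_ok and "T" in seq:
            raise ValueError(f"{path}: record {rec.id} contains T (enable dna_ok to map T->U)")
        if strict:
            seq = normalize_sequence(seq)
        else:
            seq = seq.replace("T", "U") if dna_ok else seq
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_dotbracket(path: str | Path) -> list[tuple[str, str, SecondaryStructure]]:
    """Paired-line records: '>id' header, sequence line, structure line."""
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    out = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        try:
            name = lines[i][1:].split()[0]
            seq = normalize_sequence(lines[i + 1])
            struct = SecondaryStructure(lines[i + 2])
        except IndexError:
            raise ValueError(f"{path}: truncated record {lines[i]!r}") from None
        if len(struct) != len(seq):
            raise ValueError(f"{path}: structure/sequence length mismatch for {name}")
        out.append((name, seq, struct))
        i += 3
    return out


def write_dotbracket(
    records: list[tuple[str, str, SecondaryStructure]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, seq, struct in records:
            fh.write(f">{name}\n{seq}\n{struct.dotbracket}\n")


def write_feature_table(rows: list[dict], path: str | Path) -> None:
    """Feature TSV with fixed column order; missing optionals as NA."""
    df = pd.DataFrame(rows)
    lead = [c for c in ("id", "L", "MFE", "GC", "GU", "GCU", "U", "RND", "BJK", "BJKbp", "Sil") if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


@dataclass
class RunConfig:
    """One run's configuration; every random draw flows from ``seed``."""

    bjk_grammar: str = ""
    rnd_grammar: str = ""
    engine: str = "vienna"
    window_len: int = 157
    overlap: int = 0
    classifier_features: tuple[str, ...] = ("L", "MFE", "GC", "RND")
    seed: int = 0
    u_range: tuple[float, float] | None = None
    gc_range: tuple[float, float] | None = None
    output_dir: str = "."
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        for key in ("bjk_grammar", "rnd_grammar"):
            p = getattr(cfg, key)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config references missing file {p!r}")
        if isinstance(cfg.classifier_features, list):
            cfg.classifier_features = tuple(cfg.classifier_features)
        return cfg

    def provenance(self) -> dict:
        """Hashes and seeds sufficient to reproduce a run bit-identically."""
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        prov = {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": self.seed,
        }
        for key in ("bjk_grammar", "rnd_grammar"):
            p = getattr(self, key)
            if p and Path(p).exists():
                prov[f"{key}_hash"] = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        return prov


def default_grammar_path(name: str) -> Path:
    """Path of a bundled grammar config ('g6' or 'rnd')."""
    p = Path(__file__).parent / "data" / f"{name}.cfg"
    if not p.exists():
        raise FileNotFoundError(f"no bundled grammar {name!r}")
    return p
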