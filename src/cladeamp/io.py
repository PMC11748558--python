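"""File formats and run configuration.

The pipeline touches four plain-text formats: FASTA for sequences, TSV for
every table (taxonomy, identity maps, primer reports, hits, counts),
newick for trees, and TOML for run configuration.  All TSV output carries a
provenance comment header (tool version, config hash, seed) and all
user-facing coordinates are 1-based inclusive; internal coordinates stay
0-based half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .classify_concord import RANKS

__all__ = [
    "read_fasta",
    "write_fasta",
    "Taxonomy",
    "read_taxonomy",
    "write_table",
    "read_table",
    "FamilyConfig",
    "PcrConfig",
    "ClassifierConfig",
    "RunConfig",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Accepts wrapped/unwrapped and CRLF dialects; rejects duplicate IDs and
    files whose first non-blank content is not a header line (reported
    with its line number).
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}"
                )
            break
    else:
        return []
    records = []
    seen = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(
    records: list[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class Taxonomy:
    """Per-ID ranked lineages (kingdom .. species; trailing ranks may be
    empty).  ``family(id)`` is the label used for on-/off-target calls."""

    def __init__(self, table: pd.DataFrame):
        if "id" not in table.columns:
            raise ValueError("taxonomy table must have an 'id' column")
        ranks = [c for c in table.columns if c != "id"]
        if tuple(ranks) != RANKS[: len(ranks)]:
            raise ValueError(
                f"rank columns must be a prefix of {RANKS}, got {ranks}"
            )
        if table["id"].duplicated().any():
            dup = table.loc[table["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate taxonomy ID {dup!r}")
        self.table = table.fillna("")
        self._by_id = {
            str(r["id"]): tuple(str(r[c]) for c in ranks)
            for _, r in self.table.iterrows()
        }
        self._ranks = ranks

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        lin = self._by_id[taxon_id]
        out = list(lin)
        while out and not out[-1]:
            out.pop()
        return tuple(out)

    def rank(self, taxon_id: str, rank_name: str) -> str:
        return self._by_id[taxon_id][self._ranks.index(rank_name)]

    def family(self, taxon_id: str) -> str:
        return self.rank(taxon_id, "family")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return Taxonomy(df)


def _version() -> str:
    from . import __version__

    return __version__


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
    index: bool = False,
) -> None:
    """TSV out with a provenance comment header.

    Coordinate columns in these tables are 1-based inclusive unless the
    column name says otherwise.
    """
    with open(path, "w") as fh:
        fh.write(f"# cladeamp={_version()}")
        if seed is not None:
            fh.write(f" seed={seed}")
        if config_hash is not None:
            fh.write(f" config={config_hash}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyConfig:
    name: str
    reference_id: str
    idlow: float
    idhigh: float = 100.0
    codons: int = 7
    consensus: float = 90.0
    greedy: bool = True
    overhang_fwd: str = ""
    overhang_rev: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.idlow <= self.idhigh <= 100:
            raise ValueError(f"family {self.name}: bad idlow/idhigh")
        if self.codons < 1 or not 50 < self.consensus <= 100:
            raise ValueError(f"family {self.name}: bad codons/consensus")


@dataclass(frozen=True)
class PcrConfig:
    max_mismatch: int = 2
    three_prime_exact: int = 3
    size_min: int = 50
    size_max: int = 5000

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.three_prime_exact < 0:
            raise ValueError("negative mismatch settings")
        if self.size_min > self.size_max:
            raise ValueError("size_min exceeds size_max")


@dataclass(frozen=True)
class ClassifierConfig:
    min_identity: float = 75.0
    mode: str = "nucleotide"

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity outside (0, 100]")
        if self.mode not in ("nucleotide", "translated"):
            raise ValueError("mode must be nucleotide or translated")


@dataclass
class RunConfig:
    families: dict[str, FamilyConfig] = field(default_factory=dict)
    pcr: PcrConfig = field(default_factory=PcrConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    paths: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_toml(cls, text: str, check_paths: bool = False) -> "RunConfig":
        raw = tomllib.loads(text)
        fams = {
            name: FamilyConfig(name=name, **blk)
            for name, blk in raw.get("family", {}).items()
        }
        cfg = cls(
            families=fams,
            pcr=PcrConfig(**raw.get("pcr", {})),
            classifier=ClassifierConfig(**raw.get("classifier", {})),
            paths=dict(raw.get("paths", {})),
            seed=int(raw.get("seed", 0)),
        )
        if check_paths:
            for key, p in cfg.paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"configured path {key} = {p!r} not found")
        return cfg

    @classmethod
    def load(cls, path: str | Path, check_paths: bool = True) -> "RunConfig":
        return cls.from_toml(Path(path).read_text(), check_paths=check_paths)

    def to_toml(self) -> str:
        def fmt(v) -> str:
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float)):
                return repr(v)
            return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'

        lines = [f"seed = {self.seed}", ""]
        for name in sorted(self.families):
            f = self.families[name]
            lines.append(f'[family."{name}"]')
            for fld in dataclasses.fields(f):
                if fld.name == "name":
                    continue
                lines.append(f"{fld.name} = {fmt(getattr(f, fld.name))}")
            lines.append("")
        for section, obj in (("pcr", self.pcr), ("classifier", self.classifier)):
            lines.append(f"[{section}]")
            for fld in dataclasses.fields(obj):
                lines.append(f"{fld.name} = {fmt(getattr(obj, fld.name))}")
            lines.append("")
        if self.paths:
            lines.append("[paths]")
            for k in sorted(self.paths):
                lines.append(f"{k} = {fmt(self.paths[k])}")
            lines.append("")
        return "\n".join(lines)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(self.to_toml())

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:12]
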