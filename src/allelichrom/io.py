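"""Readers/writers for the pipeline's text formats, config, and manifests.

All tables are TSV with a mandatory header; lines starting with ``#``
are comments.  BED is 0-based half-open.  Parse errors name the file,
line, and violated column contract.  Writers emit deterministic bytes
(fixed float formatting, no timestamps) so identical runs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import GeneratorConfig

FLOAT_FORMAT = "%.6g"

COUNT_COLUMNS = ["gene_id", "chrom", "region_type",
                 "n_composite", "n_mus", "n_cas"]
ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
EXTENDED_BED_COLUMNS = BED_COLUMNS + ["score_mus", "score_cas"]


class FormatError(ValueError):
    """Malformed input file; message carries file, line, and contract."""


def _read_tsv(path, required, int_cols=(), float_cols=()):
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: header lacks required columns {missing}")
    for col in int_cols:
        raw = df[col]
        try:
            df[col] = raw.astype("int64")
        except (ValueError, TypeError):
            bad = raw[~raw.str.fullmatch(r"-?\d+")]
            line = int(bad.index[0]) + 2  # header is line 1
            raise FormatError(
                f"{path}, line {line}: column {col!r} must be an integer, "
                f"got {bad.iloc[0]!r}") from None
    for col in float_cols:
        raw = df[col].replace("", "nan").replace("NA", "nan")
        try:
            df[col] = raw.astype(float)
        except (ValueError, TypeError):
            bad_mask = pd.to_numeric(raw, errors="coerce").isna() & (raw != "nan")
            line = int(df.index[bad_mask][0]) + 2
            raise FormatError(
                f"{path}, line {line}: column {col!r} must be numeric") from None
    return df


# -- count tables -----------------------------------------------------------

def read_count_table(path) -> pd.DataFrame:
    """Read an allelic count table, enforcing its invariants."""
    df = _read_tsv(path, COUNT_COLUMNS,
                   int_cols=("n_composite", "n_mus", "n_cas"))
    for col in ("n_composite", "n_mus", "n_cas"):
        bad = df[col] < 0
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise FormatError(f"{path}, line {line}: negative count in {col!r}")
    over = df["n_mus"] + df["n_cas"] > df["n_composite"]
    if over.any():
        line = int(df.index[over][0]) + 2
        raise FormatError(f"{path}, line {line}: n_mus + n_cas exceeds "
                          "n_composite")
    return df


def write_count_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = COUNT_COLUMNS + [c for c in table.columns if c not in COUNT_COLUMNS]
    table[cols].to_csv(path, sep="\t", index=False,
                       float_format=FLOAT_FORMAT)
    return path


# -- annotation -------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path, ANNOTATION_COLUMNS,
                   int_cols=("start", "end", "tss"))
    bad = df["start"] >= df["end"]
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}, line {line}: start must be < end")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(df.index[bad_strand][0]) + 2
        raise FormatError(f"{path}, line {line}: strand must be + or -")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> Path:
    path = Path(path)
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


# -- fragments (BED) --------------------------------------------------------

def read_fragments(path) -> pd.DataFrame:
    """Read fragment intervals from (extended) BED.

    Accepts either the 8-column extended BED with per-haplotype scores
    in columns 7-8, or a 6-column BED whose name field (column 4)
    carries a pre-assigned allele label in {mus, cas, neutral}.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}, line {lineno}: expected >= 6 "
                                  f"BED columns, got {len(parts)}")
            rows.append((lineno, parts))
    out = []
    extended = rows and len(rows[0][1]) >= 8
    for lineno, parts in rows:
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: start/end must be "
                              "integers") from None
        if start >= end:
            raise FormatError(f"{path}, line {lineno}: start must be < end")
        rec = {"chrom": parts[0], "start": start, "end": end,
               "name": parts[3], "score": parts[4], "strand": parts[5]}
        if extended:
            if len(parts) < 8:
                raise FormatError(f"{path}, line {lineno}: expected score_mus/"
                                  "score_cas in columns 7-8")
            try:
                rec["score_mus"] = float(parts[6])
                rec["score_cas"] = float(parts[7])
            except ValueError:
                raise FormatError(f"{path}, line {lineno}: haplotype scores "
                                  "must be numeric") from None
        else:
            if parts[3] not in ("mus", "cas", "neutral"):
                raise FormatError(
                    f"{path}, line {lineno}: name column must carry an "
                    "allele label in {mus, cas, neutral} for 6-column BED")
            rec["allele"] = parts[3]
        out.append(rec)
    return pd.DataFrame(out)


def write_fragments(fragments: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = [c for c in EXTENDED_BED_COLUMNS if c in fragments.columns]
    fragments[cols].to_csv(path, sep="\t", index=False, header=False)
    return path


# -- generic tables ---------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    """Read a TSV with automatic dtype inference (truth/density/skew)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_gene_list(path) -> list:
    """One gene id per line; blank lines and # comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


# -- run config -------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run; YAML round-trippable."""

    min_reads: int = 15
    fold: float = 2.0
    fdr_max: float = 0.05
    inbred_fold: float = 2.0
    inbred_fdr_max: float = 0.01
    pseudocount: float = 0.5
    expressed_fpkm: float = 1.0
    state_thresholds: dict | str = "fit"
    roc_cutoff_max: float = 6.0
    seed: int = 0
    generator: GeneratorConfig = dataclasses.field(
        default_factory=GeneratorConfig)
    version: str = "0.1.0"

    def validate(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.fold < 1.0 or self.inbred_fold < 1.0:
            raise ValueError("fold thresholds must be >= 1")
        for name, v in (("fdr_max", self.fdr_max),
                        ("inbred_fdr_max", self.inbred_fdr_max)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self.generator.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d["generator"]
        gen["cross_type_weights"] = {
            "-".join(k): v for k, v in gen["cross_type_weights"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "cross_type_weights" in gen:
            gen["cross_type_weights"] = {
                tuple(k.split("-")): v
                for k, v in gen["cross_type_weights"].items()}
        cfg = cls(**d, generator=GeneratorConfig(**gen))
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(config.to_yaml())
    return path


# -- manifest ---------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, stage: str, inputs: dict, outputs: dict,
                   config: dict | None = None) -> Path:
    """Deterministic per-stage manifest (content hashes, config, version).

    Appends the stage entry to ``manifest.json`` in the output
    directory; no timestamps, so reruns are byte-identical.
    """
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "version": __version__, "stages": []}
    manifest["stages"] = [s for s in manifest["stages"] if s["stage"] != stage]
    manifest["stages"].append({
        "stage": stage,
        "inputs": {k: file_sha256(v) for k, v in sorted(inputs.items())},
        "outputs": {k: file_sha256(v) for k, v in sorted(outputs.items())},
        "config": config or {}})
    manifest["stages"].sort(key=lambda s: s["stage"])
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
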