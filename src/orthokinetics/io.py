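"""Readers and writers for the pipeline's tabular file formats.

All tables are plain TSV.  Readers are strict: any malformed row raises a
:class:`TableFormatError` carrying the 1-based line number, and writers are
exact inverses of their readers (round-trip identity).  Genomic coordinates
are 1-based inclusive everywhere inside the package; BED input (0-based
half-open) is converted at the boundary.  Chromosome names are normalized by
stripping a leading ``chr`` prefix, because human and mouse annotation
sources mix the two conventions.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "TimeCourseMatrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation",
    "write_annotation_tsv",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_snp_table",
    "write_snp_table",
    "read_de_table",
    "write_de_table",
    "read_term_map",
    "write_term_map",
    "normalize_chromosome",
]

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]
SNP_COLUMNS = ["snp_id", "trait", "chrom", "pos", "pvalue"]
DE_COLUMNS = ["gene_id", "timepoint", "log2_fc", "fdr"]
ORTHOLOG_COLUMNS = ["human_gene", "mouse_gene"]


class TableFormatError(ValueError):
    """A table violated its dialect; ``line`` is the 1-based file line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


def _format_time(t: float) -> str:
    """Render a time point in hours compactly (0.5 -> '0.5', 4.0 -> '4')."""
    return f"{t:g}"


def sample_column(condition: str, timepoint: float, replicate: int) -> str:
    """Column label for one sample: ``<condition>_<time>h_r<rep>``."""
    return f"{condition}_{_format_time(timepoint)}h_r{replicate}"


@dataclass
class TimeCourseMatrix:
    """Genes x (time x replicate) expression matrix for one species/condition.

    ``values`` is indexed by gene id with one column per sample, named
    ``<condition>_<time>h_r<rep>``.  Values are RPKM (linear scale, >= 0).
    """

    species: str
    condition: str
    timepoints: tuple[float, ...]
    n_replicates: int
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")
        expected = [
            sample_column(self.condition, t, r)
            for t in self.timepoints
            for r in range(1, self.n_replicates + 1)
        ]
        if list(self.values.columns) != expected:
            raise ValueError(
                "sample columns do not match (condition, timepoint, replicate) "
                f"grid; expected {expected[:3]}..., got {list(self.values.columns)[:3]}..."
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def columns_for(self, timepoint: float) -> list[str]:
        return [
            sample_column(self.condition, timepoint, r)
            for r in range(1, self.n_replicates + 1)
        ]

    def log2_values(self) -> pd.DataFrame:
        """log2(RPKM + 1) for every sample."""
        return np.log2(self.values + 1.0)

    def replicate_mean_log2(self) -> pd.DataFrame:
        """Replicate-averaged log2(RPKM + 1): genes x timepoints."""
        logv = self.log2_values()
        out = pd.DataFrame(
            {
                _format_time(t): logv[self.columns_for(t)].mean(axis=1)
                for t in self.timepoints
            }
        )
        out.columns = list(self.timepoints)
        return out

    def subset_times(self, timepoints) -> "TimeCourseMatrix":
        """A new matrix restricted to the given (existing) time points."""
        times = tuple(float(t) for t in timepoints)
        missing = set(times) - set(self.timepoints)
        if missing:
            raise ValueError(f"timepoints not in matrix: {sorted(missing)}")
        cols = [c for t in times for c in self.columns_for(t)]
        return TimeCourseMatrix(
            species=self.species,
            condition=self.condition,
            timepoints=times,
            n_replicates=self.n_replicates,
            values=self.values[cols],
        )

    def subset(self, gene_ids) -> "TimeCourseMatrix":
        return TimeCourseMatrix(
            species=self.species,
            condition=self.condition,
            timepoints=self.timepoints,
            n_replicates=self.n_replicates,
            values=self.values.loc[list(gene_ids)],
        )


def write_expression_tsv(matrix: TimeCourseMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# species={matrix.species}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")


def _parse_sample_column(label: str, path, line: int):
    """Split '<condition>_<time>h_r<rep>' into its parts."""
    try:
        cond, rest = label.split("_", 1)
        time_part, rep_part = rest.rsplit("_r", 1)
        if not time_part.endswith("h"):
            raise ValueError
        t = float(time_part[:-1])
        rep = int(rep_part)
    except (ValueError, IndexError):
        raise TableFormatError(
            f"cannot parse sample column {label!r} as '<condition>_<time>h_r<rep>'",
            path,
            line,
        ) from None
    return cond, t, rep


def read_expression_tsv(path, species: str | None = None) -> TimeCourseMatrix:
    """Read an expression TSV written by :func:`write_expression_tsv`.

    The header row encodes condition, time point and replicate per column.
    Raises :class:`TableFormatError` (with line numbers) on duplicate gene
    ids, negative or non-numeric values, and ragged rows.
    """
    with open(path) as fh:
        lines = fh.readlines()
    lineno = 0
    file_species = None
    while lineno < len(lines) and lines[lineno].startswith("#"):
        meta = lines[lineno][1:].strip()
        if meta.startswith("species="):
            file_species = meta.split("=", 1)[1]
        lineno += 1
    if lineno >= len(lines):
        raise TableFormatError("no data rows", path)
    header = next(csv.reader([lines[lineno]], delimiter="\t"))
    header_line = lineno + 1
    if len(header) < 2 or header[0] != "gene_id":
        raise TableFormatError(
            "header must start with 'gene_id' followed by sample columns",
            path,
            header_line,
        )
    samples = [
        _parse_sample_column(c, path, header_line) for c in header[1:]
    ]
    conditions = {s[0] for s in samples}
    if len(conditions) != 1:
        raise TableFormatError(
            f"mixed conditions in one matrix: {sorted(conditions)}", path, header_line
        )
    condition = samples[0][0]
    timepoints = sorted({s[1] for s in samples})
    reps = sorted({s[2] for s in samples})
    expected = [
        sample_column(condition, t, r) for t in timepoints for r in reps
    ]
    if header[1:] != expected or reps != list(range(1, len(reps) + 1)):
        raise TableFormatError(
            "sample columns must enumerate every (timepoint, replicate) in "
            "time-major order with replicates r1..rN",
            path,
            header_line,
        )

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    ncol = len(header)
    for offset, raw in enumerate(lines[header_line:], start=header_line + 1):
        if not raw.strip():
            continue
        fields = next(csv.reader([raw], delimiter="\t"))
        if len(fields) != ncol:
            raise TableFormatError(
                f"ragged row: expected {ncol} fields, got {len(fields)}",
                path,
                offset,
            )
        gid = fields[0]
        if gid in seen:
            raise TableFormatError(f"duplicate gene id {gid!r}", path, offset)
        seen.add(gid)
        try:
            vals = [float(v) for v in fields[1:]]
        except ValueError:
            raise TableFormatError(
                f"non-numeric expression value in row for {gid!r}", path, offset
            ) from None
        for v in vals:
            if not np.isfinite(v):
                raise TableFormatError(
                    f"non-finite expression value for {gid!r}", path, offset
                )
            if v < 0:
                raise TableFormatError(
                    f"negative RPKM value {v} for gene {gid!r}", path, offset
                )
        gene_ids.append(gid)
        rows.append(vals)
    if not rows:
        raise TableFormatError("no data rows", path)
    values = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"),
                          columns=header[1:])
    return TimeCourseMatrix(
        species=species or file_species or "unknown",
        condition=condition,
        timepoints=tuple(timepoints),
        n_replicates=len(reps),
        values=values,
    )


# ---------------------------------------------------------------------------
# Gene annotation


def normalize_chromosome(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def _check_chrom_mixing(raw_names) -> None:
    prefixed = {n for n in raw_names if n.lower().startswith("chr")}
    bare = set(raw_names) - prefixed
    if prefixed and bare:
        warnings.warn(
            "mixed chromosome naming ('chr1' and '1'); normalizing to "
            "un-prefixed names",
            stacklevel=3,
        )


def _validate_annotation(df: pd.DataFrame, path=None) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise TableFormatError(f"duplicate gene ids: {list(dups)[:5]}", path)
    if (df["start"] <= 0).any() or (df["end"] <= 0).any():
        raise TableFormatError("coordinates must be positive", path)
    bad = df["start"] > df["end"]
    if bad.any():
        gid = df.loc[bad, "gene_id"].iloc[0]
        raise TableFormatError(f"start > end for gene {gid!r}", path)
    if not df["strand"].isin(["+", "-"]).all():
        raise TableFormatError("strand must be '+' or '-'", path)
    return df.reset_index(drop=True)


def read_annotation(path, format: str = "tsv") -> pd.DataFrame:
    """Read a gene annotation as a DataFrame with columns
    ``gene_id, chrom, start, end, strand, biotype`` (1-based inclusive).

    ``format`` is one of ``gtf``, ``bed`` (BED3+name[+score+strand],
    0-based half-open, converted here) or ``tsv`` (the package's own
    column-named dialect).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise TableFormatError(f"missing columns {missing}", path, 1)
    elif format == "bed":
        df = _read_bed(path)
    elif format == "gtf":
        df = _read_gtf(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    _check_chrom_mixing(df["chrom"])
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chromosome)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return _validate_annotation(df[ANNOTATION_COLUMNS], path)


def _read_bed(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise TableFormatError(
                    "BED needs at least 4 columns (chrom, start, end, name)",
                    path,
                    lineno,
                )
            chrom, start0, end0, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            biotype = fields[6] if len(fields) >= 7 else "coding"
            try:
                start0, end0 = int(start0), int(end0)
            except ValueError:
                raise TableFormatError("non-integer BED coordinates", path, lineno) from None
            if start0 >= end0:
                raise TableFormatError("BED start must be < end", path, lineno)
            records.append(
                # 0-based half-open -> 1-based inclusive
                dict(gene_id=name, chrom=chrom, start=start0 + 1, end=end0,
                     strand=strand, biotype=biotype)
            )
    if not records:
        raise TableFormatError("no data rows", path)
    return pd.DataFrame.from_records(records)


def _read_gtf(path) -> pd.DataFrame:
    from gffutils.feature import feature_from_line

    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            try:
                feat = feature_from_line(raw, dialect=None)
            except Exception as exc:  # gffutils raises plain Exceptions
                raise TableFormatError(f"unparseable GTF line: {exc}", path, lineno)
            if feat.featuretype != "gene":
                continue
            attrs = feat.attributes
            gid = (attrs.get("gene_id") or [None])[0]
            if gid is None:
                raise TableFormatError("gene feature without gene_id", path, lineno)
            biotype = (
                attrs.get("gene_biotype") or attrs.get("gene_type") or ["coding"]
            )[0]
            if feat.start > feat.end:
                raise TableFormatError(
                    f"start > end for gene {gid!r}", path, lineno
                )
            records.append(
                dict(gene_id=gid, chrom=feat.seqid, start=feat.start,
                     end=feat.end, strand=feat.strand or "+", biotype=biotype)
            )
    if not records:
        raise TableFormatError("no gene features found", path)
    return pd.DataFrame.from_records(records)


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ortholog map, SNP catalog, DE table, term map


def read_ortholog_map(path) -> pd.DataFrame:
    """Two-column TSV ``human_gene<TAB>mouse_gene``; enforces one-to-one."""
    with open(path) as fh:
        rows = []
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise TableFormatError("ortholog map needs two columns", path, lineno)
            if lineno == 1 and fields[:2] == ORTHOLOG_COLUMNS:
                continue
            rows.append((fields[0], fields[1]))
    if not rows:
        raise TableFormatError("no data rows", path)
    df = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
    for col in ORTHOLOG_COLUMNS:
        dup = df[col].duplicated()
        if dup.any():
            offenders = sorted(df.loc[dup, col].unique())
            raise TableFormatError(
                f"one-to-one violated: {col} appears in multiple pairs: "
                f"{offenders[:5]}",
                path,
            )
    return df


def write_ortholog_map(pairs: pd.DataFrame, path) -> None:
    pairs[ORTHOLOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    """SNP catalog TSV: ``snp_id, trait, chrom, pos, pvalue``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str,
                                            "trait": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing columns {missing}", path, 1)
    if (df["pos"] <= 0).any():
        line = int(df.index[df["pos"] <= 0][0]) + 2
        raise TableFormatError("SNP position must be positive", path, line)
    bad_p = (df["pvalue"] <= 0) | (df["pvalue"] > 1)
    if bad_p.any():
        line = int(df.index[bad_p][0]) + 2
        raise TableFormatError("p-value must be in (0, 1]", path, line)
    _check_chrom_mixing(df["chrom"])
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chromosome)
    return df[SNP_COLUMNS].reset_index(drop=True)


def write_snp_table(snps: pd.DataFrame, path) -> None:
    snps[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression TSV: ``gene_id, timepoint, log2_fc, fdr``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing columns {missing}", path, 1)
    dup = df.duplicated(subset=["gene_id", "timepoint"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise TableFormatError(
            "duplicate (gene, timepoint) record", path, line
        )
    bad = (df["fdr"] < 0) | (df["fdr"] > 1)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise TableFormatError("FDR must be in [0, 1]", path, line)
    return df[DE_COLUMNS].reset_index(drop=True)


def write_de_table(de: pd.DataFrame, path) -> None:
    de[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_term_map(path) -> dict[str, set[str]]:
    """Term-to-genes TSV (``term<TAB>gene`` rows) -> dict of gene sets."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise TableFormatError("term map needs two columns", path, lineno)
            if lineno == 1 and fields[:2] == ["term", "gene"]:
                continue
            terms.setdefault(fields[0], set()).add(fields[1])
    if not terms:
        raise TableFormatError("no data rows", path)
    return terms


def write_term_map(terms: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tgene\n")
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{term}\t{gene}\n")
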