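"""On-disk formats and in-memory containers for the methylation pipeline.

All internal genomic positions are 1-based (the Bismark coverage
convention); conversion to 0-based half-open happens only when writing
BED. Methylation is stored as integer (methylated, total) read counts;
ratios are derived, with a missing value (NaN) wherever total == 0 —
zero methylation is a real level and is never used to encode missingness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGSite",
    "MethylationCountMatrix",
    "MethylationRatioMatrix",
    "SampleSheet",
    "GeneModel",
    "CoverageParseError",
    "read_coverage_file",
    "read_coverage_files",
    "write_coverage_file",
    "write_ratio_table",
    "read_ratio_table",
    "write_dmr_table",
    "write_dmr_bed",
    "read_gene_models",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_celltype_reference",
    "write_celltype_reference",
]

GROUPS = ("ER", "NR", "PR")

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "group", "sex", "age", "bmi", "smoker",
    "med_atypical", "med_antidepressant", "med_anticonvulsant",
    "n_psychotropics", "current_li",
]


class CoverageParseError(ValueError):
    """A coverage file line could not be parsed."""


@dataclass(frozen=True, order=True)
class CpGSite:
    """A single CpG position. ``pos`` is the 1-based cytosine coordinate."""

    chrom: str
    pos: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")


def _check_sorted_unique(chroms: np.ndarray, pos: np.ndarray) -> None:
    for c in pd.unique(chroms):
        p = pos[chroms == c]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"sites on {c} are not strictly increasing")


@dataclass
class MethylationCountMatrix:
    """Per-CpG, per-sample (methylated, total) read counts.

    ``chrom``/``pos``/``strand`` are parallel arrays of length n_sites,
    sorted by (chrom, pos) with no duplicate (chrom, pos). ``meth`` and
    ``total`` are (n_sites, n_samples) non-negative integer arrays with
    ``meth <= total`` elementwise.
    """

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    strand: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        n = len(self.pos)
        if self.strand is None:
            self.strand = np.full(n, ".", dtype=object)
        if len(self.chrom) != n:
            raise ValueError("chrom/pos length mismatch")
        if self.meth.shape != (n, len(self.samples)) or self.total.shape != self.meth.shape:
            raise ValueError("count matrix dimensions inconsistent with sites/samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.meth > self.total):
            raise ValueError("meth > total at some site")
        if np.any(self.pos < 1):
            raise ValueError("positions must be 1-based (>= 1)")
        _check_sorted_unique(self.chrom, self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sites(self) -> list[CpGSite]:
        return [CpGSite(c, int(p), s) for c, p, s in zip(self.chrom, self.pos, self.strand)]

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.chrom, self.pos], names=["chrom", "pos"])

    def subset_sites(self, mask: np.ndarray) -> "MethylationCountMatrix":
        mask = np.asarray(mask)
        return MethylationCountMatrix(
            self.chrom[mask], self.pos[mask], list(self.samples),
            self.meth[mask], self.total[mask], self.strand[mask],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationCountMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return MethylationCountMatrix(
            self.chrom, self.pos, list(sample_ids),
            self.meth[:, idx], self.total[:, idx], self.strand,
        )


@dataclass
class MethylationRatioMatrix:
    """Per-CpG methylation ratios in [0, 1]; NaN where total was 0."""

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    ratio: np.ndarray
    strand: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ratio = np.asarray(self.ratio, dtype=float)
        n = len(self.pos)
        if self.strand is None:
            self.strand = np.full(n, ".", dtype=object)
        if self.ratio.shape != (n, len(self.samples)):
            raise ValueError("ratio matrix dimensions inconsistent")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.ratio, initial=0.0) < 0 or np.nanmax(self.ratio, initial=0.0) > 1:
                raise ValueError("ratios must lie in [0, 1]")
        _check_sorted_unique(self.chrom, self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.chrom, self.pos], names=["chrom", "pos"])

    def subset_sites(self, mask: np.ndarray) -> "MethylationRatioMatrix":
        mask = np.asarray(mask)
        return MethylationRatioMatrix(
            self.chrom[mask], self.pos[mask], list(self.samples),
            self.ratio[mask], self.strand[mask],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationRatioMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return MethylationRatioMatrix(
            self.chrom, self.pos, list(sample_ids), self.ratio[:, idx], self.strand,
        )


class SampleSheet:
    """Cohort metadata: response group plus the covariates used for
    matching and confounder adjustment.

    Groups are ER (excellent responder, Alda total >= 7), NR
    (non-responder, Alda <= 3) and PR (partial responder, in between).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {bad}")
        for col in ("smoker", "med_atypical", "med_antidepressant",
                    "med_anticonvulsant", "current_li"):
            df[col] = df[col].astype(bool)
        if (df["n_psychotropics"] < 1).any():
            raise ValueError("n_psychotropics must be >= 1")
        if "alda_total" in df.columns and df["alda_total"].notna().any():
            a = df["alda_total"]
            er_bad = ((df["group"] == "ER") & a.notna() & (a < 7)).any()
            nr_bad = ((df["group"] == "NR") & a.notna() & (a > 3)).any()
            pr_bad = ((df["group"] == "PR") & a.notna() & ~a.between(4, 6)).any()
            if er_bad or nr_bad or pr_bad:
                raise ValueError("group labels inconsistent with Alda totals "
                                 "(ER requires >= 7, NR requires <= 3)")
        self.df = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.df["sample_id"])

    def group_of(self, sample_id: str) -> str:
        return self.df.set_index("sample_id").loc[sample_id, "group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.df.loc[self.df["group"] == group, "sample_id"])

    def group_labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        m = self.df.set_index("sample_id")["group"]
        return m.loc[list(sample_ids)].to_numpy()

    def covariate(self, name: str, sample_ids: Sequence[str]) -> np.ndarray:
        m = self.df.set_index("sample_id")[name]
        return m.loc[list(sample_ids)].to_numpy()


@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TTS and 1-based inclusive exons."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c <= b:
                raise ValueError("exons overlap")
        if self.strand == "+" and self.tss > self.tts:
            raise ValueError("+ strand gene must have tss <= tts")
        if self.strand == "-" and self.tss < self.tts:
            raise ValueError("- strand gene must have tss >= tts")

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts)


# ---------------------------------------------------------------------------
# Bismark coverage files


def read_coverage_file(path: str | Path) -> pd.DataFrame:
    """Parse one Bismark-style coverage file.

    Expected tab-separated columns: chrom, start, end, methylation
    percentage, methylated count, unmethylated count; start == end,
    1-based. A methylation percentage inconsistent with the counts
    beyond rounding triggers a warning, not an error.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}")
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
                pct = float(parts[3])
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise CoverageParseError(f"{path}:{lineno}: {exc}") from None
            if not chrom or start < 1 or n_meth < 0 or n_unmeth < 0:
                raise CoverageParseError(f"{path}:{lineno}: invalid field values")
            total = n_meth + n_unmeth
            if total > 0 and abs(pct - 100.0 * n_meth / total) > 0.51:
                warnings.warn(
                    f"{path}:{lineno}: methylation % {pct} inconsistent with "
                    f"counts {n_meth}/{total}", stacklevel=2)
            rows.append((chrom, start, n_meth, total))
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])


def read_coverage_files(paths: Sequence[str | Path],
                        sample_ids: Sequence[str] | None = None,
                        ) -> MethylationCountMatrix:
    """Read per-sample coverage files into one count matrix.

    Sites are the union across samples; a site absent from a sample has
    total 0 there. Sample ids default to file stems (``.cov`` stripped).
    """
    paths = [Path(p) for p in paths]
    if sample_ids is None:
        sample_ids = [p.name.removesuffix(".gz").removesuffix(".cov") for p in paths]
    frames = []
    for sid, p in zip(sample_ids, paths):
        df = read_coverage_file(p)
        df["sample"] = sid
        frames.append(df)
    alldf = pd.concat(frames, ignore_index=True)
    meth = alldf.pivot_table(index=["chrom", "pos"], columns="sample",
                             values="meth", fill_value=0, aggfunc="sum")
    total = alldf.pivot_table(index=["chrom", "pos"], columns="sample",
                              values="total", fill_value=0, aggfunc="sum")
    meth = meth.reindex(columns=sample_ids).sort_index()
    total = total.reindex(columns=sample_ids).sort_index()
    chrom = meth.index.get_level_values(0).to_numpy(dtype=object)
    pos = meth.index.get_level_values(1).to_numpy(dtype=np.int64)
    return MethylationCountMatrix(chrom, pos, list(sample_ids),
                                  meth.to_numpy(), total.to_numpy())


def write_coverage_file(m: MethylationCountMatrix, sample_id: str,
                        path: str | Path) -> None:
    """Write one sample's counts as a Bismark coverage file, omitting
    uncovered sites (total 0), as Bismark itself would."""
    j = m.samples.index(sample_id)
    with open(path, "w") as fh:
        for i in range(m.n_sites):
            tot = int(m.total[i, j])
            if tot == 0:
                continue
            me = int(m.meth[i, j])
            pct = 100.0 * me / tot
            fh.write(f"{m.chrom[i]}\t{int(m.pos[i])}\t{int(m.pos[i])}\t"
                     f"{pct:.6g}\t{me}\t{tot - me}\n")


# ---------------------------------------------------------------------------
# metilene-style ratio table


def write_ratio_table(m: MethylationRatioMatrix, path: str | Path,
                      sheet: SampleSheet | None = None,
                      precision: int = 5) -> None:
    """Write a metilene-style ratio table (chr, pos, one column per
    sample). With a sample sheet, columns are blocked by group
    (ER, NR, PR); missing ratios are written as ``.``."""
    order = list(m.samples)
    if sheet is not None:
        order = [s for g in GROUPS for s in sheet.samples_in(g) if s in m.samples]
        leftover = [s for s in m.samples if s not in order]
        order += leftover
    idx = [m.samples.index(s) for s in order]
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        fh.write("chr\tpos\t" + "\t".join(order) + "\n")
        for i in range(m.n_sites):
            vals = []
            for j in idx:
                r = m.ratio[i, j]
                vals.append("." if math.isnan(r) else fmt.format(r))
            fh.write(f"{m.chrom[i]}\t{int(m.pos[i])}\t" + "\t".join(vals) + "\n")


def read_ratio_table(path: str | Path) -> MethylationRatioMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    samples = list(df.columns[2:])
    df = df.sort_values(["chr", "pos"], kind="stable")
    return MethylationRatioMatrix(
        df["chr"].to_numpy(dtype=object), df["pos"].to_numpy(dtype=np.int64),
        samples, df[samples].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# DMR output

DMR_TABLE_COLUMNS = ["dmr_id", "chrom", "start", "end", "n_cpgs",
                     "mean_meth_er", "mean_meth_nr", "mean_diff", "p", "q",
                     "location", "gene", "cpg_positions"]


def write_dmr_table(dmrs: Iterable, path: str | Path) -> None:
    """Write the DMR table as TSV (1-based inclusive coordinates)."""
    rows = []
    for d in dmrs:
        rows.append({
            "dmr_id": d.dmr_id, "chrom": d.chrom, "start": d.start,
            "end": d.end, "n_cpgs": d.n_cpgs,
            "mean_meth_er": round(d.mean_meth_er, 4),
            "mean_meth_nr": round(d.mean_meth_nr, 4),
            "mean_diff": round(d.mean_diff, 4),
            "p": d.p, "q": d.q,
            "location": getattr(d, "location", "") or "",
            "gene": getattr(d, "gene", "") or "",
            "cpg_positions": ",".join(str(p) for p in d.cpg_positions),
        })
    pd.DataFrame(rows, columns=DMR_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dmr_table(path: str | Path) -> list:
    """Read a DMR table written by :func:`write_dmr_table`."""
    from .dmr import DMR

    df = pd.read_csv(path, sep="\t", dtype={"location": str, "gene": str},
                     keep_default_na=False, na_values=[""])
    out = []
    for _, r in df.iterrows():
        out.append(DMR(
            dmr_id=str(r["dmr_id"]), chrom=str(r["chrom"]),
            start=int(r["start"]), end=int(r["end"]),
            cpg_positions=[int(x) for x in str(r["cpg_positions"]).split(",")],
            mean_meth_er=float(r["mean_meth_er"]),
            mean_meth_nr=float(r["mean_meth_nr"]),
            mean_diff=float(r["mean_diff"]),
            p=float(r["p"]), q=float(r["q"]),
            location=(r["location"] if isinstance(r["location"], str)
                      and r["location"] else None),
            gene=(r["gene"] if isinstance(r["gene"], str) and r["gene"]
                  else None)))
    return out


def bed_score(q: float) -> int:
    """-10·log10(q), rounded, clipped to the BED score range [0, 1000]."""
    if q <= 0:
        return 1000
    return int(min(1000, max(0, round(-10.0 * math.log10(q)))))


def write_dmr_bed(dmrs: Iterable, path: str | Path) -> None:
    """Write DMRs as BED6+ (0-based half-open). Extra columns:
    n_cpgs, mean_diff, p, q, location class, gene."""
    with open(path, "w") as fh:
        for d in dmrs:
            fh.write("\t".join(map(str, [
                d.chrom, d.start - 1, d.end, d.dmr_id, bed_score(d.q), ".",
                d.n_cpgs, f"{d.mean_diff:.4f}", f"{d.p:.6g}", f"{d.q:.6g}",
                getattr(d, "location", "") or ".",
                getattr(d, "gene", "") or ".",
            ])) + "\n")


# ---------------------------------------------------------------------------
# Gene models


def _gene_models_from_gff(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes = []
    for g in db.features_of_type("gene"):
        if g.strand not in ("+", "-"):
            warnings.warn(f"gene {g.id} has no strand; skipped", stacklevel=2)
            continue
        name = (g.attributes.get("gene_name") or g.attributes.get("Name")
                or g.attributes.get("gene_id") or [g.id])[0]
        gid = (g.attributes.get("gene_id") or [g.id])[0]
        exons = [(e.start, e.end) for e in db.children(g, featuretype="exon")]
        # Collapse identical/overlapping exons across transcripts.
        merged: list[tuple[int, int]] = []
        for a, b in sorted(set(exons)):
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        tss, tts = (g.start, g.end) if g.strand == "+" else (g.end, g.start)
        genes.append(GeneModel(gid, name, g.seqid, g.strand, tss, tts, merged))
    return genes


def _gene_models_from_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom, cstart, cend, name, _score, strand = f[:6]
            if strand not in ("+", "-"):
                warnings.warn(f"{path}:{lineno}: no strand; gene skipped", stacklevel=2)
                continue
            start0, end0 = int(cstart), int(cend)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start0 + o + 1, start0 + o + s) for o, s in zip(offsets, sizes)]
            start1, end1 = start0 + 1, end0
            tss, tts = (start1, end1) if strand == "+" else (end1, start1)
            genes.append(GeneModel(name, name, chrom, strand, tss, tts, exons))
    return genes


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF/GFF (gene + exon features) or BED12."""
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _gene_models_from_bed12(path)
    return _gene_models_from_gff(path)


# ---------------------------------------------------------------------------
# Sample sheet and cell-type reference CSVs


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, index=False)


def read_celltype_reference(path: str | Path):
    """Reference CSV: columns chrom, pos, then one column per cell type."""
    from .deconvolution import CellTypeReference

    df = pd.read_csv(path)
    types = [c for c in df.columns if c not in ("chrom", "pos")]
    df = df.sort_values(["chrom", "pos"], kind="stable")
    return CellTypeReference(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        cell_types=types,
        profile=df[types].to_numpy(dtype=float))


def write_celltype_reference(ref, path: str | Path) -> None:
    df = pd.DataFrame({"chrom": ref.chrom, "pos": ref.pos})
    for j, t in enumerate(ref.cell_types):
        df[t] = ref.profile[:, j]
    df.to_csv(path, index=False)
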