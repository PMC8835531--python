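"""Readers, writers and validated in-memory containers for every external
format the pipeline touches.

Internal coordinates are 1-based inclusive throughout (the GFF3 convention);
BED export/import converts to 0-based half-open at the boundary.

Formats
-------
SNP counts   PoPoolation2 ``sync`` (A:T:C:G:N:del per population, collapsed
             to biallelic) or a native two-column ref/alt count table.
Design       CSV/TSV with columns ``population, treatment, stratum``.
Metabolites  CSV: ``sample_id, population_id, <metabolite columns...>``.
Sets         GMT: ``set_id <TAB> description <TAB> member...``.
Annotation   GFF3 in (via gffutils), BED out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SchemaError",
    "SnpCountTable",
    "StudyDesign",
    "MetaboliteMatrix",
    "MetaboliteSetLibrary",
    "GeneAnnotation",
    "read_snp_table",
    "write_snp_table",
    "read_design",
    "write_design",
    "read_metabolites",
    "write_metabolites",
    "read_gmt",
    "write_gmt",
    "read_gff",
    "write_bed",
    "read_bed",
]

_NUCS = ("A", "T", "C", "G")


class FormatError(ValueError):
    """A line could not be parsed in the declared dialect."""


class SchemaError(ValueError):
    """The file parsed but violates a structural invariant."""


# ---------------------------------------------------------------------------
# SnpCountTable


@dataclass
class SnpCountTable:
    """Per-SNP, per-population biallelic read counts with genomic coordinates.

    Invariants (enforced by :meth:`validate`): counts are non-negative
    integers with one (ref, alt) pair per population per SNP, and
    (chrom, pos) pairs are unique and sorted by position within chromosome.
    """

    chrom: np.ndarray  # (n_snps,) str
    pos: np.ndarray  # (n_snps,) int, 1-based
    ref: np.ndarray  # (n_snps, n_pops) int
    alt: np.ndarray  # (n_snps, n_pops) int
    populations: list[str]
    ref_base: np.ndarray | None = None  # optional per-SNP nucleotide labels
    alt_base: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.populations = list(self.populations)
        if self.ref_base is None:
            self.ref_base = np.full(len(self.pos), "A", dtype=object)
        if self.alt_base is None:
            self.alt_base = np.full(len(self.pos), "T", dtype=object)
        self.ref_base = np.asarray(self.ref_base, dtype=object)
        self.alt_base = np.asarray(self.alt_base, dtype=object)
        self.validate()

    # -- basic accessors ----------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def coverage(self) -> np.ndarray:
        """(n_snps, n_pops) read depth per cell."""
        return self.ref + self.alt

    def alt_frequencies(self) -> np.ndarray:
        """Alt-allele frequency alt/(ref+alt); raises on zero coverage."""
        cov = self.coverage()
        if np.any(cov == 0):
            raise ValueError("zero coverage cell encountered; filter first")
        return self.alt / cov

    def validate(self) -> None:
        n, p = self.ref.shape
        if self.alt.shape != (n, p) or len(self.chrom) != n or len(self.pos) != n:
            raise SchemaError("count array shapes inconsistent with coordinates")
        if p != len(self.populations):
            raise SchemaError(
                f"{p} count columns but {len(self.populations)} population ids"
            )
        if np.any(self.ref < 0) or np.any(self.alt < 0):
            raise SchemaError("negative read counts")
        if np.any(self.pos < 1):
            raise SchemaError("positions must be 1-based (>= 1)")
        keys = list(zip(self.chrom, self.pos))
        if len(set(keys)) != n:
            raise SchemaError("duplicate (chrom, pos) pairs")
        for c in pd.unique(self.chrom):
            sub = self.pos[self.chrom == c]
            if np.any(np.diff(sub) <= 0):
                raise SchemaError(f"positions not sorted within chromosome {c!r}")

    def subset(self, mask: np.ndarray) -> "SnpCountTable":
        mask = np.asarray(mask)
        return SnpCountTable(
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.populations,
            self.ref_base[mask],
            self.alt_base[mask],
        )

    def snp_index(self) -> dict[tuple[str, int], int]:
        return {(c, int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.pos))}


# ---------------------------------------------------------------------------
# StudyDesign


@dataclass
class StudyDesign:
    """Population -> (treatment, replicate stratum) assignment.

    Strata are matched replicate sets: within a stratum there is at most one
    population per treatment. Treatment column ordering for the CMH scan is
    the sorted unique treatment labels.
    """

    populations: list[str]
    treatments: np.ndarray  # (n_pops,) str
    strata: np.ndarray  # (n_pops,) int

    def __post_init__(self) -> None:
        self.populations = list(self.populations)
        self.treatments = np.asarray(self.treatments, dtype=object)
        self.strata = np.asarray(self.strata, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n = len(self.populations)
        if len(self.treatments) != n or len(self.strata) != n:
            raise SchemaError("design arrays have inconsistent lengths")
        if len(set(self.populations)) != n:
            raise SchemaError("duplicate population id in design")
        if any(t is None or str(t) == "" for t in self.treatments):
            raise SchemaError("empty treatment label")
        seen: set[tuple[int, str]] = set()
        for s, t in zip(self.strata, self.treatments):
            key = (int(s), str(t))
            if key in seen:
                raise SchemaError(
                    f"stratum {s} contains two populations of treatment {t!r}"
                )
            seen.add(key)

    @property
    def treatment_levels(self) -> list[str]:
        return sorted(set(map(str, self.treatments)))

    @property
    def stratum_levels(self) -> list[int]:
        return sorted(set(map(int, self.strata)))

    @property
    def n_treatments(self) -> int:
        return len(self.treatment_levels)

    @property
    def n_strata(self) -> int:
        return len(self.stratum_levels)

    def treatment_of(self) -> dict[str, str]:
        return {p: str(t) for p, t in zip(self.populations, self.treatments)}

    def layout(self, populations: list[str]) -> np.ndarray:
        """(K, J) index of each stratum/treatment cell into ``populations``.

        Cells with no population are -1 (the CMH scan drops such strata).
        Raises if a design population is missing from ``populations``.
        """
        idx = {p: i for i, p in enumerate(populations)}
        missing = [p for p in self.populations if p not in idx]
        if missing:
            raise KeyError(f"design populations absent from table: {missing}")
        tlev = {t: j for j, t in enumerate(self.treatment_levels)}
        slev = {s: k for k, s in enumerate(self.stratum_levels)}
        out = np.full((self.n_strata, self.n_treatments), -1, dtype=np.int64)
        for p, t, s in zip(self.populations, self.treatments, self.strata):
            out[slev[int(s)], tlev[str(t)]] = idx[p]
        return out


# ---------------------------------------------------------------------------
# MetaboliteMatrix


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance matrix plus sample -> population map.

    ``abundance`` is indexed by sample_id with one numeric column per
    metabolite; ``sample_populations`` maps each sample to its population
    (or treatment label when population resolution is absent).
    """

    abundance: pd.DataFrame
    sample_populations: pd.Series

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.sample_populations.index):
            raise SchemaError("sample ids of abundance and population map differ")
        vals = self.abundance.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise SchemaError("non-numeric abundance values")
        if not np.all(np.isfinite(vals)):
            raise SchemaError("non-finite abundance values (apply imputation?)")

    @property
    def metabolites(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)

    def population_means(self) -> pd.DataFrame:
        """Mean abundance per population (rows) per metabolite (columns)."""
        return self.abundance.groupby(self.sample_populations).mean()


# ---------------------------------------------------------------------------
# MetaboliteSetLibrary


@dataclass
class MetaboliteSetLibrary:
    """Named metabolite sets plus the reference metabolome they live in."""

    sets: dict[str, list[str]]
    reference: list[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = set(self.reference)
        pruned = {}
        for sid, members in self.sets.items():
            kept = [m for m in dict.fromkeys(members) if m in ref]
            if kept:
                pruned[sid] = kept
        self.sets = pruned

    @property
    def set_ids(self) -> list[str]:
        return sorted(self.sets)


# ---------------------------------------------------------------------------
# GeneAnnotation


@dataclass
class GeneAnnotation:
    """Gene spans, 1-based inclusive, strand carried but never interpreted."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(self.genes.columns):
            raise SchemaError(f"annotation missing columns {required - set(self.genes.columns)}")
        if (self.genes["start"] > self.genes["end"]).any():
            raise SchemaError("gene with start > end")
        self.genes = self.genes.reset_index(drop=True)

    def check_namespace(self, chroms: set[str]) -> None:
        unknown = set(self.genes["chrom"]) - set(chroms)
        if unknown:
            warnings.warn(
                f"annotation chromosomes not present in SNP table: {sorted(unknown)}",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# SNP table I/O


def _collapse_sync_counts(counts: np.ndarray, ref_base: str):
    """Collapse (n_pops, 6) A:T:C:G:N:del counts to biallelic ref/alt.

    The two alleles are the nucleotides with the highest summed counts
    across populations; the file's reference base keeps the 'ref' role when
    it is one of them.
    """
    totals = counts[:, :4].sum(axis=0)
    order = np.argsort(totals, kind="stable")[::-1]
    top2 = [int(order[0]), int(order[1])]
    ref_i = _NUCS.index(ref_base) if ref_base in _NUCS else -1
    if ref_i in top2:
        a_ref = ref_i
        a_alt = top2[0] if top2[1] == ref_i else top2[1]
    else:
        a_ref, a_alt = top2
    return counts[:, a_ref], counts[:, a_alt], _NUCS[a_ref], _NUCS[a_alt]


def read_snp_table(path, dialect: str = "sync") -> SnpCountTable:
    """Read a SNP count table in ``sync`` or ``counts`` dialect."""
    if dialect == "sync":
        return _read_sync(path)
    if dialect == "counts":
        return _read_counts(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_sync(path) -> SnpCountTable:
    chroms, poss, refs, alts, rb, ab = [], [], [], [], [], []
    n_pops = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: expected >= 4 tab fields")
            if n_pops is None:
                n_pops = len(fields) - 3
            elif len(fields) - 3 != n_pops:
                raise SchemaError(
                    f"line {lineno}: {len(fields) - 3} population columns, expected {n_pops}"
                )
            try:
                pos = int(fields[1])
            except ValueError as e:
                raise FormatError(f"line {lineno}: bad position {fields[1]!r}") from e
            counts = np.zeros((n_pops, 6), dtype=np.int64)
            for i, cell in enumerate(fields[3:]):
                parts = cell.split(":")
                if len(parts) != 6:
                    raise FormatError(
                        f"line {lineno}: population column {i + 1} is not A:T:C:G:N:del"
                    )
                try:
                    counts[i] = [int(x) for x in parts]
                except ValueError as e:
                    raise FormatError(
                        f"line {lineno}: non-integer count in column {i + 1}"
                    ) from e
            r, a, rbase, abase = _collapse_sync_counts(counts, fields[2].upper())
            chroms.append(fields[0])
            poss.append(pos)
            refs.append(r)
            alts.append(a)
            rb.append(rbase)
            ab.append(abase)
    if n_pops is None:
        raise FormatError("empty sync file")
    pops = [f"pop{i + 1}" for i in range(n_pops)]
    return SnpCountTable(
        np.array(chroms, dtype=object), np.array(poss), np.array(refs),
        np.array(alts), pops, np.array(rb, dtype=object), np.array(ab, dtype=object),
    )


def _read_counts(path) -> SnpCountTable:
    df = pd.read_csv(path, sep="\t")
    fixed = ["chrom", "pos", "ref_base", "alt_base"]
    if list(df.columns[:4]) != fixed:
        raise SchemaError(f"counts dialect requires leading columns {fixed}")
    pops = []
    for col in df.columns[4:]:
        if col.endswith(".ref"):
            pops.append(col[:-4])
        elif not col.endswith(".alt"):
            raise SchemaError(f"unexpected column {col!r} (want <pop>.ref / <pop>.alt)")
    for p in pops:
        for suffix in (".ref", ".alt"):
            if p + suffix not in df.columns:
                raise SchemaError(f"population {p!r} missing column {p + suffix!r}")
    bad = df[[p + s for p in pops for s in (".ref", ".alt")]].isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        raise SchemaError(f"row {row + 2}: missing population count")
    ref = df[[p + ".ref" for p in pops]].to_numpy(dtype=np.int64)
    alt = df[[p + ".alt" for p in pops]].to_numpy(dtype=np.int64)
    return SnpCountTable(
        df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(dtype=np.int64),
        ref, alt, pops,
        df["ref_base"].to_numpy(dtype=object), df["alt_base"].to_numpy(dtype=object),
    )


def write_snp_table(table: SnpCountTable, path, dialect: str = "counts") -> None:
    """Write a count table; ``counts`` is the canonical round-trip dialect."""
    if dialect == "counts":
        cols = {"chrom": table.chrom, "pos": table.pos,
                "ref_base": table.ref_base, "alt_base": table.alt_base}
        for i, p in enumerate(table.populations):
            cols[p + ".ref"] = table.ref[:, i]
            cols[p + ".alt"] = table.alt[:, i]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    elif dialect == "sync":
        with open(path, "w") as fh:
            for i in range(table.n_snps):
                cells = []
                for j in range(table.n_populations):
                    c = [0] * 6
                    rbase = table.ref_base[i]
                    abase = table.alt_base[i]
                    c[_NUCS.index(rbase)] = int(table.ref[i, j])
                    c[_NUCS.index(abase)] = int(table.alt[i, j])
                    cells.append(":".join(map(str, c)))
                fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref_base[i]}\t"
                         + "\t".join(cells) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# design / metabolites / GMT


def read_design(path) -> StudyDesign:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"population": str, "treatment": str})
    required = {"population", "treatment", "stratum"}
    if not required.issubset(df.columns):
        raise SchemaError(f"design file missing columns {required - set(df.columns)}")
    if df["treatment"].isna().any() or (df["treatment"].astype(str).str.strip() == "").any():
        raise SchemaError("empty treatment label in design file")
    return StudyDesign(
        df["population"].tolist(),
        df["treatment"].to_numpy(dtype=object),
        df["stratum"].to_numpy(dtype=np.int64),
    )


def write_design(design: StudyDesign, path) -> None:
    pd.DataFrame({
        "population": design.populations,
        "treatment": design.treatments,
        "stratum": design.strata,
    }).to_csv(path, index=False)


def read_metabolites(path, impute: str | None = None) -> MetaboliteMatrix:
    """Read a sample x metabolite CSV.

    Missing cells raise unless ``impute='halfmin'``, which fills each
    metabolite's missing values with half its observed minimum (a common
    MS detection-limit convention).
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "population_id": str})
    for col in ("sample_id", "population_id"):
        if col not in df.columns:
            raise SchemaError(f"metabolite file missing column {col!r}")
    df = df.set_index("sample_id")
    pops = df.pop("population_id")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            sample = newly_bad.idxmax()
            raise FormatError(
                f"non-numeric abundance at sample {sample!r}, metabolite {col!r}"
            )
        df[col] = coerced
    if df.isna().to_numpy().any():
        if impute == "halfmin":
            df = df.fillna(df.min() / 2.0)
        else:
            sample = df.index[df.isna().any(axis=1)][0]
            raise SchemaError(
                f"missing abundance values (first at sample {sample!r}); "
                "pass impute='halfmin' to fill"
            )
    return MetaboliteMatrix(df, pops)


def write_metabolites(matrix: MetaboliteMatrix, path) -> None:
    out = matrix.abundance.copy()
    out.insert(0, "population_id", matrix.sample_populations)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_gmt(path, reference: list[str] | None = None) -> MetaboliteSetLibrary:
    """Read a GMT file. When ``reference`` is None it is the union of members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: GMT needs id, description, >=1 member")
            sets[fields[0]] = fields[2:]
            descriptions[fields[0]] = fields[1]
    if reference is None:
        reference = sorted({m for members in sets.values() for m in members})
    return MetaboliteSetLibrary(sets, list(reference), descriptions)


def write_gmt(library: MetaboliteSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for sid in library.set_ids:
            desc = library.descriptions.get(sid, "")
            fh.write("\t".join([sid, desc] + list(library.sets[sid])) + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED


def read_gff(path, feature_type: str = "gene") -> GeneAnnotation:
    """Extract gene spans from a GFF3 file (via gffutils, in-memory DB)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand or "."))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals (chrom, start, end, name[, score])
    as 0-based half-open BED."""
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            fields = [str(row["chrom"]), str(int(row["start"]) - 1), str(int(row["end"]))]
            if "name" in intervals.columns:
                fields.append(str(row["name"]))
                if "score" in intervals.columns:
                    fields.append(str(row["score"]))
            fh.write("\t".join(fields) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED back into 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 fields")
            row = {"chrom": f[0], "start": int(f[1]) + 1, "end": int(f[2])}
            if len(f) > 3:
                row["name"] = f[3]
            if len(f) > 4:
                row["score"] = float(f[4])
            rows.append(row)
    return pd.DataFrame(rows)
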