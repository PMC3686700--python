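"""Genotype/pedigree/phenotype containers, file IO, QC filtering and imputation.

Dosages are counts of the "A" (counted) allele in {0, 1, 2}, stored as floats
with NaN marking missing calls so that mean-imputed (fractional) dosages flow
through downstream linear models unchanged. Marker positions are 1-based bp.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PedigreeTable",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "qc_filter",
    "drop_monomorphic",
    "impute_missing",
    "average_phenotypes",
]

UNKNOWN_PARENT = "0"


@dataclass
class GenotypeMatrix:
    """n individuals x m SNPs allele-dosage matrix with its marker map.

    Parameters
    ----------
    dosages
        (n, m) float array with entries in {0, 1, 2} or NaN (missing).
        Fractional entries are permitted after imputation.
    ids
        Individual identifiers, length n.
    marker_map
        DataFrame with columns ``snp_id``, ``lg``, ``bp`` (1-based), one row
        per dosage column, sorted by (lg, bp).
    """

    dosages: np.ndarray
    ids: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if len(self.ids) != n:
            raise ValueError("ids length does not match dosage rows")
        if len(self.marker_map) != m:
            raise ValueError("marker map must have one row per SNP column")
        required = {"snp_id", "lg", "bp"}
        if not required.issubset(self.marker_map.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if self.marker_map["snp_id"].duplicated().any():
            raise ValueError("duplicated snp_ids in marker map")
        keys = self.marker_map[["lg", "bp"]].to_numpy()
        if not (pd.DataFrame(keys).apply(tuple, axis=1).is_monotonic_increasing):
            raise ValueError("marker map must be sorted by (lg, bp)")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self.marker_map = self.marker_map.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.marker_map["snp_id"].to_numpy()

    def allele_freqs(self) -> np.ndarray:
        """Frequency p_i of the counted allele, from observed calls only."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.ids,
            self.marker_map.loc[mask].reset_index(drop=True),
        )

    def subset_individuals(self, keep) -> "GenotypeMatrix":
        idx = _index_of(self.ids, keep)
        return GenotypeMatrix(self.dosages[idx], self.ids[idx], self.marker_map)


def _index_of(ids: np.ndarray, wanted) -> np.ndarray:
    pos = {v: i for i, v in enumerate(ids)}
    try:
        return np.array([pos[w] for w in wanted], dtype=int)
    except KeyError as e:  # pragma: no cover - defensive
        raise KeyError(f"unknown individual id {e.args[0]!r}") from None


@dataclass
class PedigreeTable:
    """Individual/sire/dam records; ``"0"`` marks an unknown parent.

    Records must be topologically orderable (no individual is its own
    ancestor); founders are rows with both parents unknown.
    """

    records: pd.DataFrame  # columns: id, sire, dam (str)

    def __post_init__(self) -> None:
        df = self.records.copy()
        for c in ("id", "sire", "dam"):
            if c not in df.columns:
                raise ValueError("pedigree needs columns id, sire, dam")
            df[c] = df[c].astype(str)
        if df["id"].duplicated().any():
            raise ValueError("duplicated individual ids in pedigree")
        self.records = df.reset_index(drop=True)
        self.topological_order()  # raises on cycles

    @property
    def ids(self) -> np.ndarray:
        return self.records["id"].to_numpy()

    def founders(self) -> np.ndarray:
        r = self.records
        mask = (r["sire"] == UNKNOWN_PARENT) & (r["dam"] == UNKNOWN_PARENT)
        return r.loc[mask, "id"].to_numpy()

    def parents_of(self, ind: str) -> tuple[str, str]:
        row = self.records.loc[self.records["id"] == ind]
        if row.empty:
            raise KeyError(ind)
        return row["sire"].iloc[0], row["dam"].iloc[0]

    def topological_order(self) -> list[str]:
        """Ids ordered so every parent precedes its offspring (Kahn)."""
        r = self.records
        known = set(r["id"])
        deps = {
            row.id: {p for p in (row.sire, row.dam) if p in known}
            for row in r.itertuples()
        }
        children: dict[str, list[str]] = {i: [] for i in deps}
        for child, parents in deps.items():
            for p in parents:
                children[p].append(child)
        order: list[str] = []
        ready = [i for i, d in deps.items() if not d]
        while ready:
            nxt = ready.pop()
            order.append(nxt)
            for c in children[nxt]:
                deps[c].discard(nxt)
                if not deps[c]:
                    ready.append(c)
        if len(order) != len(deps):
            raise ValueError("pedigree contains a cycle")
        return order


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

_VCF_HEADER = "##fileformat=VCFv4.2"


def write_genotypes(g: GenotypeMatrix, path, fmt: str = "tabular") -> None:
    """Write a genotype matrix as unphased GT-only VCF or as a dosage table.

    The tabular dialect is a TSV with individuals as rows, SNPs as columns and
    values 0/1/2/NA; fractional (imputed) dosages are written as-is.
    """
    path = Path(path)
    if fmt == "tabular":
        df = pd.DataFrame(g.dosages, index=g.ids, columns=g.snp_ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t", na_rep="NA")
    elif fmt == "vcf":
        frac = g.dosages[~np.isnan(g.dosages)] % 1
        if frac.size and np.any(frac != 0):
            raise ValueError("VCF output requires integer dosages (GT field)")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER + "\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, g.ids))
                + "\n"
            )
            for j, row in enumerate(g.marker_map.itertuples()):
                calls = [
                    "./." if np.isnan(d) else gt_map[d] for d in g.dosages[:, j]
                ]
                fh.write(
                    f"{row.lg}\t{row.bp}\t{row.snp_id}\tA\tB\t.\tPASS\t.\tGT\t"
                    + "\t".join(calls)
                    + "\n"
                )
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes(path, fmt: str = "tabular") -> GenotypeMatrix:
    """Read genotypes from VCF (ALT-allele dosage) or the tabular dialect.

    For VCF input the counted allele is ALT: GT 0/0 -> 0, 0/1 -> 1, 1/1 -> 2.
    Multi-allelic VCF records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tabular":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        mm = pd.DataFrame(
            {"snp_id": df.columns, "lg": 0, "bp": np.arange(1, df.shape[1] + 1)}
        )
        return GenotypeMatrix(df.to_numpy(dtype=float), df.index.to_numpy(), mm)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        import cyvcf2
    except ImportError:
        cyvcf2 = None
    if cyvcf2 is not None:
        vcf = cyvcf2.VCF(str(path))
        ids = np.array(vcf.samples, dtype=object)
        rows, recs = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
            gts = np.array(var.genotypes, dtype=object)
            dos = np.array(
                [np.nan if a[0] < 0 or a[1] < 0 else float(a[0] + a[1]) for a in gts]
            )
            rows.append(dos)
            recs.append((var.ID, int(var.CHROM), var.POS))
        vcf.close()
    else:  # plain-text GT fallback
        rows, recs, ids = [], [], None
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    ids = np.array(fields[9:], dtype=object)
                    continue
                if "," in fields[4]:
                    raise ValueError(
                        f"multi-allelic record at {fields[0]}:{fields[1]}"
                    )
                dos = []
                for call in fields[9:]:
                    gt = call.split(":")[0].replace("|", "/")
                    if "." in gt:
                        dos.append(np.nan)
                    else:
                        dos.append(float(sum(int(a) for a in gt.split("/"))))
                rows.append(np.array(dos))
                recs.append((fields[2], int(fields[0]), int(fields[1])))
        if ids is None:
            raise ValueError("malformed VCF: missing #CHROM header line")
    mm = pd.DataFrame(recs, columns=["snp_id", "lg", "bp"])
    dosages = np.array(rows).T if rows else np.empty((len(ids), 0))
    order = np.lexsort((mm["bp"], mm["lg"]))
    mm = mm.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(dosages[:, order], ids, mm)


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.records.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> PedigreeTable:
    return PedigreeTable(pd.read_csv(path, sep="\t", dtype=str))


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# QC, imputation, phenotype averaging
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Per-filter SNP drop counts, in application order."""

    n_input: int
    n_dropped_missing: int
    n_dropped_mendel: int
    n_retained: int
    max_missing: float
    max_mendel_rate: float
    empty_result: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def qc_filter(
    g: GenotypeMatrix,
    ped: PedigreeTable | None = None,
    max_missing: float = 0.05,
    max_mendel_rate: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Call-level QC: missingness filter, then Mendelian-consistency filter.

    A SNP is dropped if its missing fraction exceeds ``max_missing``, then
    (among survivors) if its rate of opposite-homozygote parent-offspring
    conflicts over informative genotyped pairs exceeds ``max_mendel_rate``.
    Without a pedigree (or with ungenotyped parents) the Mendel step is a
    no-op for the affected SNPs/pairs.
    """
    n_in = g.n_snps
    keep = g.missing_fraction() <= max_missing
    n_miss = int(np.sum(~keep))
    g1 = g.subset_snps(keep)

    n_mendel = 0
    if ped is not None and g1.n_snps:
        rate = _mendel_conflict_rate(g1, ped)
        keep2 = ~(rate > max_mendel_rate)  # NaN rate (no informative pairs) kept
        n_mendel = int(np.sum(~keep2))
        g1 = g1.subset_snps(keep2)

    report = QCReport(
        n_input=n_in,
        n_dropped_missing=n_miss,
        n_dropped_mendel=n_mendel,
        n_retained=g1.n_snps,
        max_missing=max_missing,
        max_mendel_rate=max_mendel_rate,
        empty_result=g1.n_snps == 0,
    )
    return g1, report


def _mendel_conflict_rate(g: GenotypeMatrix, ped: PedigreeTable) -> np.ndarray:
    """Opposite-homozygote conflict rate per SNP over parent-offspring pairs."""
    pos = {v: i for i, v in enumerate(g.ids)}
    pairs = []
    for row in ped.records.itertuples():
        if row.id not in pos:
            continue
        for parent in (row.sire, row.dam):
            if parent != UNKNOWN_PARENT and parent in pos:
                pairs.append((pos[row.id], pos[parent]))
    if not pairs:
        return np.full(g.n_snps, np.nan)
    off = g.dosages[[p[0] for p in pairs]]
    par = g.dosages[[p[1] for p in pairs]]
    informative = ~(np.isnan(off) | np.isnan(par))
    conflict = informative & (np.abs(off - par) == 2)
    n_inf = informative.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_inf > 0, conflict.sum(axis=0) / n_inf, np.nan)


def drop_monomorphic(g: GenotypeMatrix) -> GenotypeMatrix:
    """Drop SNPs with no observed variation (required before VanRaden G)."""
    p = g.allele_freqs()
    keep = (p > 0) & (p < 1)
    return g.subset_snps(keep)


def impute_missing(g: GenotypeMatrix, method: str = "mean_dosage") -> GenotypeMatrix:
    """Replace missing dosages by the SNP's observed mean dosage.

    Observed entries are unchanged, so allele-frequency estimates from
    observed calls are preserved exactly. Raises on an all-missing SNP.
    """
    if method != "mean_dosage":
        raise ValueError(f"unknown imputation method {method!r}")
    d = g.dosages.copy()
    missing = np.isnan(d)
    if np.any(missing.all(axis=0)):
        bad = g.snp_ids[missing.all(axis=0)]
        raise ValueError(f"all-missing SNP(s): {list(bad[:5])}")
    if missing.any():
        col_mean = np.nanmean(d, axis=0)
        d[missing] = np.broadcast_to(col_mean, d.shape)[missing]
    return GenotypeMatrix(d, g.ids, g.marker_map)


def average_phenotypes(
    raw: pd.DataFrame,
    id_col: str = "id",
    year_col: str = "year",
    trait_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Two-stage phenotype averaging: fruit replicates within year, then years.

    ``raw`` holds one row per fruit/replicate measurement with an individual
    id, a year label and trait columns; returns one analysis value per
    individual per trait (NaN where an individual has no records for a trait).
    """
    if trait_cols is None:
        trait_cols = [c for c in raw.columns if c not in (id_col, year_col)]
    within_year = (
        raw.groupby([id_col, year_col])[trait_cols].mean().reset_index()
    )
    over_years = within_year.groupby(id_col)[trait_cols].mean().reset_index()
    return over_years
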