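"""Readers and writers for strain-panel data.

On-disk formats
---------------
* genotypes: project TSV (``chrom  pos  id  ref  alt  <strain...>``, calls
  ``0``/``1``/``.``) or VCF 4.x restricted to biallelic SNPs,
* phenotypes: CSV with a ``strain`` column and one column per trait,
* gene annotation: BED (0-based half-open, ``name`` field = gene name),
* result tables: TSV.

Positions are 1-based on disk (TSV and VCF) and 0-based half-open
internally; the conversion happens here and nowhere else.  Missing
genotype calls are a single sentinel (:data:`MISSING`); there is no
imputation.  Strain-name matching is exact and case-sensitive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .trait_integration import GeneScore

#: Sentinel call code for a missing genotype.
MISSING = -1

#: Token written for a missing call in the TSV dialect.  ``NA`` is also
#: accepted on input.
MISSING_TOKEN = "."


class PanelValidationError(ValueError):
    """A structural invariant of a panel object is violated."""


class PanelParseError(ValueError):
    """An input file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainPanel:
    """Ordered collection of unique strain names."""

    strain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.strain_ids) < 3:
            raise PanelValidationError(
                f"panel needs >= 3 strains, got {len(self.strain_ids)}"
            )
        if any(not s for s in self.strain_ids):
            raise PanelValidationError("empty strain name")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            dupes = sorted(
                {s for s in self.strain_ids if self.strain_ids.count(s) > 1}
            )
            raise PanelValidationError(f"duplicate strain name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.strain_ids)

    def __iter__(self):
        return iter(self.strain_ids)

    def index_of(self, strain: str) -> int:
        try:
            return self.strain_ids.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain {strain!r}") from None


@dataclass
class GenotypeMatrix:
    """Strains x biallelic SNP sites, homozygous calls only.

    ``calls`` is an ``(n_strains, n_sites)`` int8 array with values in
    ``{0, 1, MISSING}``.  Sites are sorted by ``(chromosome, position)``
    and positions are unique within a chromosome.
    """

    panel: StrainPanel
    chrom: np.ndarray  # (n_sites,) object
    pos: np.ndarray  # (n_sites,) int64, 0-based
    site_id: np.ndarray  # (n_sites,) object
    ref: np.ndarray  # (n_sites,) object
    alt: np.ndarray  # (n_sites,) object
    calls: np.ndarray  # (n_strains, n_sites) int8

    def __post_init__(self) -> None:
        n_sites = len(self.chrom)
        for name in ("pos", "site_id", "ref", "alt"):
            if len(getattr(self, name)) != n_sites:
                raise PanelValidationError(f"site array {name!r} length mismatch")
        if self.calls.shape != (len(self.panel), n_sites):
            raise PanelValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.panel)}, {n_sites})"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise PanelValidationError(
                f"calls must be 0, 1 or {MISSING}; found {self.calls[bad][0]}"
            )
        order = _site_order(self.chrom, self.pos)
        if not np.array_equal(order, np.arange(n_sites)):
            raise PanelValidationError(
                "sites not sorted by (chromosome, position); "
                "use GenotypeMatrix.from_arrays(resort=True)"
            )
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(np.unique(p)) != len(p):
                raise PanelValidationError(f"duplicate position on {c}")

    @classmethod
    def from_arrays(
        cls,
        panel: StrainPanel,
        chrom: Iterable[str],
        pos: Iterable[int],
        site_id: Iterable[str],
        ref: Iterable[str],
        alt: Iterable[str],
        calls: np.ndarray,
        resort: bool = False,
    ) -> "GenotypeMatrix":
        chrom = np.asarray(list(chrom), dtype=object)
        pos = np.asarray(list(pos), dtype=np.int64)
        site_id = np.asarray(list(site_id), dtype=object)
        ref = np.asarray(list(ref), dtype=object)
        alt = np.asarray(list(alt), dtype=object)
        calls = np.asarray(calls, dtype=np.int8)
        order = _site_order(chrom, pos)
        if resort and not np.array_equal(order, np.arange(len(chrom))):
            warnings.warn("genotype sites were not sorted; re-sorting", stacklevel=2)
            chrom, pos, site_id, ref, alt = (
                a[order] for a in (chrom, pos, site_id, ref, alt)
            )
            calls = calls[:, order]
        return cls(panel, chrom, pos, site_id, ref, alt, calls)

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    @property
    def n_strains(self) -> int:
        return len(self.panel)

    def chromosome_ranges(self) -> list[tuple[str, int, int]]:
        """Contiguous ``(chromosome, start_index, stop_index)`` site runs."""
        out: list[tuple[str, int, int]] = []
        i = 0
        while i < self.n_sites:
            j = i
            while j < self.n_sites and self.chrom[j] == self.chrom[i]:
                j += 1
            out.append((self.chrom[i], i, j))
            i = j
        return out


def _site_order(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    return np.lexsort((pos, chrom.astype(str)))


@dataclass(frozen=True)
class GeneRecord:
    name: str
    chromosome: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelValidationError(
                f"gene {self.name}: start {self.start} >= end {self.end}"
            )


@dataclass
class GeneAnnotation:
    """Gene intervals with unique names, 0-based half-open coordinates."""

    records: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelValidationError(f"duplicate gene name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> GeneRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.records)


@dataclass
class PhenotypeTable:
    """Strain-level mean trait values; NaN marks an absent measurement."""

    values: pd.DataFrame  # index = strain, columns = traits, float

    def __post_init__(self) -> None:
        finite = self.values.to_numpy(dtype=float)
        if np.isinf(finite).any():
            raise PanelValidationError("phenotype values must be finite")
        if self.values.index.duplicated().any():
            raise PanelValidationError("duplicate strain rows in phenotype table")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    def trait_values(self, trait: str) -> dict[str, float]:
        """Strain -> value mapping for one trait, absent values dropped."""
        col = self.values[trait]
        return {s: float(v) for s, v in col.items() if math.isfinite(v)}

    def check_panel(self, panel: StrainPanel) -> None:
        """Every phenotyped strain must exist in the genotype panel."""
        extra = [s for s in self.strains if s not in panel.strain_ids]
        if extra:
            raise PanelValidationError(
                f"strain(s) in phenotypes but not in genotypes: {extra}"
            )


# ---------------------------------------------------------------------------
# genotype loaders
# ---------------------------------------------------------------------------

_TSV_FIXED = ("chrom", "pos", "id", "ref", "alt")


def load_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Load a genotype matrix from ``tsv`` or ``vcf``.

    VCF genotypes map 0/0 -> 0, 1/1 -> 1 and anything else (missing or
    heterozygous) to :data:`MISSING`; non-biallelic or non-SNP records
    are skipped with a warning.
    """
    if format == "tsv":
        return _load_genotypes_tsv(Path(path))
    if format == "vcf":
        return _load_genotypes_vcf(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _load_genotypes_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[: len(_TSV_FIXED)]) != _TSV_FIXED:
            raise PanelParseError(
                f"{path}: header must start with {' '.join(_TSV_FIXED)}"
            )
        strains = header[len(_TSV_FIXED):]
        if len(set(strains)) != len(strains):
            raise PanelValidationError(f"{path}: duplicate strain column")
        panel = StrainPanel(tuple(strains))
        chrom, pos, site_id, ref, alt, rows = [], [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise PanelParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            try:
                p = int(parts[1])
            except ValueError:
                raise PanelParseError(
                    f"{path}:{lineno}: non-integer position {parts[1]!r}"
                ) from None
            chrom.append(parts[0])
            pos.append(p - 1)  # 1-based on disk
            site_id.append(parts[2])
            ref.append(parts[3])
            alt.append(parts[4])
            row = []
            for tok in parts[5:]:
                if tok in (MISSING_TOKEN, "NA", ""):
                    row.append(MISSING)
                elif tok in ("0", "1"):
                    row.append(int(tok))
                else:
                    raise PanelParseError(
                        f"{path}:{lineno}: invalid call {tok!r}"
                    )
            rows.append(row)
    calls = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(panel), 0), dtype=np.int8)
    )
    return GenotypeMatrix.from_arrays(
        panel, chrom, pos, site_id, ref, alt, calls, resort=True
    )


def _load_genotypes_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        strains = list(vf.header.samples)
        if len(set(strains)) != len(strains):
            raise PanelValidationError(f"{path}: duplicate sample name")
        panel = StrainPanel(tuple(strains))
        chrom, pos, site_id, ref, alt, cols = [], [], [], [], [], []
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                warnings.warn(
                    f"{path}: skipping non-biallelic-SNP record at "
                    f"{rec.chrom}:{rec.pos}",
                    stacklevel=2,
                )
                continue
            col = np.full(len(panel), MISSING, dtype=np.int8)
            for i, s in enumerate(strains):
                gt = rec.samples[s].get("GT")
                if gt == (0, 0):
                    col[i] = 0
                elif gt == (1, 1):
                    col[i] = 1
                # ./., 0/1 etc. stay MISSING
            chrom.append(rec.chrom)
            pos.append(rec.pos - 1)  # pysam rec.pos is 1-based
            site_id.append(rec.id or f"{rec.chrom}:{rec.pos}")
            ref.append(rec.ref)
            alt.append(alts[0])
            cols.append(col)
    calls = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((len(panel), 0), dtype=np.int8)
    )
    return GenotypeMatrix.from_arrays(
        panel, chrom, pos, site_id, ref, alt, calls, resort=True
    )


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_FIXED + tuple(gm.panel)) + "\n")
        for j in range(gm.n_sites):
            calls = [
                MISSING_TOKEN if c == MISSING else str(int(c))
                for c in gm.calls[:, j]
            ]
            fh.write(
                "\t".join(
                    [
                        gm.chrom[j],
                        str(int(gm.pos[j]) + 1),
                        gm.site_id[j],
                        gm.ref[j],
                        gm.alt[j],
                    ]
                    + calls
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# phenotype / annotation loaders
# ---------------------------------------------------------------------------


def load_phenotypes(path: str | Path) -> PhenotypeTable:
    """Load a strain x trait CSV; empty cells become absent values."""
    raw = pd.read_csv(path, dtype=str)
    if "strain" not in raw.columns:
        raise PanelParseError(f"{path}: missing required 'strain' column")
    traits = [c for c in raw.columns if c != "strain"]
    if not traits:
        raise PanelParseError(f"{path}: no trait columns")
    strains = raw["strain"].tolist()
    data = {}
    for trait in traits:
        col = []
        for i, tok in enumerate(raw[trait]):
            if tok is None or (isinstance(tok, float) and math.isnan(tok)) or (
                isinstance(tok, str) and not tok.strip()
            ):
                col.append(math.nan)
                continue
            try:
                col.append(float(tok))
            except ValueError:
                raise PanelParseError(
                    f"{path}: non-numeric value {tok!r} for "
                    f"trait {trait!r}, strain {strains[i]!r}"
                ) from None
        data[trait] = col
    frame = pd.DataFrame(data, index=pd.Index(strains, name="strain"))
    return PhenotypeTable(frame)


def write_phenotypes_csv(table: PhenotypeTable, path: str | Path) -> None:
    table.values.to_csv(path, index_label="strain", float_format="%.17g")


def load_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Load gene intervals from a BED file (name field = gene name)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise PanelParseError(
                    f"{path}:{lineno}: BED needs chrom, start, end, name"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise PanelParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            records.append(GeneRecord(parts[3], parts[0], start, end))
    return GeneAnnotation(tuple(records))


def write_gene_annotation_bed(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ann:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_rank_table(scores: "list[GeneScore]", path: str | Path) -> None:
    """Write a ranked gene table.

    Columns: gene, per-trait p / FDR p / removed flag, the display Score
    (1 decimal, mirroring published tables), the full-precision score and
    the 1-based rank.  Rows are sorted by descending score with ties
    broken by gene name.
    """
    from .trait_integration import rank_genes

    if not scores:
        raise ValueError("no scores to write")
    ranked = rank_genes(scores)
    traits = list(ranked[0].contributions.keys())
    cols = ["gene"]
    for t in traits:
        cols += [f"p_{t}", f"fdr_p_{t}", f"removed_{t}"]
    cols += ["score_display", "score", "rank"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for gs in ranked:
            row = [gs.gene_name]
            for t in traits:
                p = gs.trait_p.get(t)
                fdr = gs.trait_fdr_p.get(t)
                rem = gs.trait_removed.get(t)
                row.append("NA" if p is None else f"{p:.17g}")
                row.append("NA" if fdr is None else f"{fdr:.17g}")
                row.append("NA" if rem is None else str(int(rem)))
            row.append(f"{gs.score:.1f}")
            row.append(f"{gs.score:.17g}")
            row.append(str(gs.rank))
            fh.write("\t".join(row) + "\n")


def read_rank_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trait_results(results, path: str | Path) -> None:
    """Persist per-(gene, trait) mapping results as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "gene\ttrait\tp_orig\tstatus\tn_blocks_tested\t"
            "best_chrom\tbest_start\tbest_end\n"
        )
        for r in results:
            if r.p_orig is None:
                p, bc, bs, be = "NA", "NA", "NA", "NA"
            else:
                p = f"{r.p_orig:.17g}"
                bc = r.best_block.chromosome
                bs = str(r.best_block.start)
                be = str(r.best_block.end)
            fh.write(
                f"{r.gene_name}\t{r.trait_name}\t{p}\t{r.status}\t"
                f"{r.n_blocks_tested}\t{bc}\t{bs}\t{be}\n"
            )


def read_trait_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_fdr_results(results, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\ttrait\tp_orig\tk\tB\tfdr_p\tremoved\treason\n")
        for r in results:
            p = "NA" if r.p_orig is None else f"{r.p_orig:.17g}"
            fh.write(
                f"{r.gene_name}\t{r.trait_name}\t{p}\t{r.k}\t{r.B}\t"
                f"{r.fdr_p:.17g}\t{int(r.removed)}\t{r.reason or ''}\n"
            )


def read_fdr_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False
    )
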