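"""Core containers for inbred-line genotype panels.

Lines are fully inbred, so every genotype is a homozygote and a single
haploid allele code per cell suffices: 0, 1, or :data:`MISSING` (-1).
Heterozygous calls found in external files are treated as missing (with a
warning), which is the only coding consistent with the downstream
haplotype-based algorithms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("wheatimpute")

#: Sentinel for a missing allele call in int8 genotype matrices.
MISSING: int = -1


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Per-marker chromosome assignment and centimorgan position.

    Positions must be strictly increasing within each chromosome; marker
    identifiers must be unique. The map defines the linear marker order
    used by all map-dependent algorithms.
    """

    marker_ids: np.ndarray          # dtype=object / str, shape (m,)
    chromosome: np.ndarray          # int, shape (m,)
    position_cm: np.ndarray         # float, shape (m,)
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_ids", np.asarray(self.marker_ids, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=np.int64))
        object.__setattr__(self, "position_cm", np.asarray(self.position_cm, dtype=float))
        m = len(self.marker_ids)
        if not (len(self.chromosome) == len(self.position_cm) == m):
            raise ValueError("map columns have inconsistent lengths")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker_id in genetic map")
        if np.any(self.position_cm < 0):
            raise ValueError("negative cM position")
        for c in np.unique(self.chromosome):
            pos = self.position_cm[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "_index", {mid: i for i, mid in enumerate(self.marker_ids)})

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def n_chromosomes(self) -> int:
        return len(np.unique(self.chromosome))

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]

    def chromosome_slices(self) -> dict[int, np.ndarray]:
        """Marker indices per chromosome, in map order."""
        return {int(c): np.flatnonzero(self.chromosome == c)
                for c in np.unique(self.chromosome)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "chrom": self.chromosome,
            "pos_cM": self.position_cm,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(df["marker_id"].to_numpy(dtype=object),
                   df["chrom"].to_numpy(),
                   df["pos_cM"].to_numpy())

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """A lines x markers matrix of haploid-equivalent allele calls.

    ``calls`` is int8 over {0, 1, MISSING}. Marker order is aligned with
    the :class:`GeneticMap` the panel was built against.
    """

    line_ids: np.ndarray            # object, shape (n,)
    marker_ids: np.ndarray          # object, shape (m,)
    calls: np.ndarray               # int8, shape (n, m)

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("calls shape inconsistent with id lists")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must be coded 0/1/MISSING")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.line_ids.copy(), self.marker_ids.copy(), self.calls.copy())

    def allele_freq(self) -> np.ndarray:
        """Observed allele-1 frequency per marker (NaN if fully missing)."""
        obs = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs.any(axis=0),
                            np.where(self.calls == 1, 1.0, 0.0).sum(axis=0)
                            / np.maximum(obs.sum(axis=0), 1),
                            np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- plain-text TSV interchange -------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls.astype(float), index=self.line_ids,
                          columns=self.marker_ids)
        df[self.calls == MISSING] = np.nan
        df.index.name = "line_id"
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", index_col="line_id")
        vals = df.to_numpy(dtype=float)
        het = (vals != 0) & (vals != 1) & np.isfinite(vals)
        if het.any():
            warnings.warn(f"{het.sum()} non-homozygote calls treated as missing")
            vals[het] = np.nan
        calls = np.where(np.isfinite(vals), vals, MISSING).astype(np.int8)
        return cls(df.index.to_numpy(dtype=object),
                   df.columns.to_numpy(dtype=object), calls)


# ---------------------------------------------------------------------------
# array design (high-density set vs nested low-density subset)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrayDesign:
    """Nested marker-array design: all markers vs a low-density subset.

    ``impute_set`` — high minus low — are the targets of low-to-high
    imputation for lines typed only on the low-density array.
    """

    high_set: np.ndarray
    low_set: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "high_set", np.asarray(self.high_set, dtype=object))
        object.__setattr__(self, "low_set", np.asarray(self.low_set, dtype=object))
        low = set(self.low_set)
        high = set(self.high_set)
        if not low < high:
            raise ValueError("low_set must be a proper subset of high_set")

    @property
    def impute_set(self) -> np.ndarray:
        low = set(self.low_set)
        return np.array([m for m in self.high_set if m not in low], dtype=object)

    def low_mask(self, marker_ids: np.ndarray) -> np.ndarray:
        """Boolean mask over ``marker_ids``: True where marker is on the low array."""
        low = set(self.low_set)
        return np.array([m in low for m in marker_ids])


# ---------------------------------------------------------------------------
# VCF interchange (haploid coded as homozygous diploid)
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, gmap: GeneticMap, path) -> None:
    """Write a plain-text VCF; 0 -> 0/0, 1 -> 1/1, missing -> ./.

    Physical positions are synthesised from cM rank (1-based running index)
    since the panel carries genetic-map coordinates only; the true cM
    position is stored in INFO/CM.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position in cM">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in np.unique(gmap.chromosome):
        header.contigs.add(str(c))
    for lid in panel.line_ids:
        header.add_sample(str(lid))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, idx in gmap.chromosome_slices().items():
            for rank, j in enumerate(idx, start=1):
                rec = out.new_record(contig=str(chrom), start=rank - 1,
                                     alleles=("A", "T"), id=str(gmap.marker_ids[j]))
                rec.info["CM"] = float(gmap.position_cm[j])
                for i in range(panel.n_lines):
                    g = panel.calls[i, j]
                    rec.samples[i]["GT"] = (None, None) if g == MISSING else (int(g), int(g))
                out.write(rec)


def read_vcf(path) -> tuple[GenotypePanel, GeneticMap]:
    """Read a VCF written by :func:`write_vcf` (or any biallelic VCF).

    Heterozygous genotypes become missing with a warning. cM positions are
    taken from INFO/CM when present, else from POS.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        mids, chroms, poss, cols = [], [], [], []
        n_het = 0
        for rec in vf:
            mids.append(rec.id)
            chroms.append(int(rec.chrom))
            poss.append(float(rec.info.get("CM", rec.pos)))
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or None in gt:
                    continue
                if len(set(gt)) > 1:
                    n_het += 1
                    continue
                col[i] = gt[0]
            cols.append(col)
    if n_het:
        warnings.warn(f"{n_het} heterozygous VCF genotypes treated as missing")
    calls = np.stack(cols, axis=1)
    gmap = GeneticMap(np.array(mids, dtype=object), np.array(chroms), np.array(poss))
    panel = GenotypePanel(np.array(samples, dtype=object), gmap.marker_ids, calls)
    return panel, gmap
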