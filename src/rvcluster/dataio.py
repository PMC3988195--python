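"""Genotype/phenotype containers, readers and writers, and the common-variant filter.

The unit of analysis is a :class:`GenotypePanel`: a subjects × sites matrix of
minor-allele counts over a single genomic region, with per-site base-pair
positions.  Genotypes can be loaded from VCF (biallelic SNVs, diploid GT) or
from a plain tab-separated matrix; phenotypes are binary case/control labels
aligned to the panel's subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class NothingToTestError(ValueError):
    """Raised when no polymorphic rare site survives filtering."""


@dataclass(frozen=True)
class GenotypePanel:
    """Subjects × sites minor-allele count matrix for one region.

    Attributes
    ----------
    subject_ids : tuple of str
        Opaque subject identifiers, one per matrix row.
    site_ids : tuple of str
        Opaque site identifiers, one per matrix column.
    positions : ndarray of int
        1-based base-pair coordinate per site, strictly increasing.
    counts : ndarray of int8, shape (n_subjects, n_sites)
        Minor-allele counts in {0, 1, 2}; missingness is not representable
        (subjects with missing genotypes are dropped at load).
    """

    subject_ids: tuple
    site_ids: tuple
    positions: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        pos = np.asarray(self.positions, dtype=np.int64)
        cnt = np.asarray(self.counts, dtype=np.int8)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "counts", cnt)
        if cnt.ndim != 2 or cnt.shape[0] < 1 or cnt.shape[1] < 1:
            raise ValueError("counts must be a non-empty 2-D subjects x sites matrix")
        if len(self.subject_ids) != cnt.shape[0]:
            raise ValueError("subject_ids length does not match counts rows")
        if len(self.site_ids) != cnt.shape[1]:
            raise ValueError("site_ids length does not match counts columns")
        if pos.shape != (cnt.shape[1],):
            raise ValueError("positions length does not match number of sites")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(cnt, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype count outside {{0,1,2}} for subject "
                f"{self.subject_ids[i]!r}, site {self.site_ids[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    def subset_sites(self, mask) -> "GenotypePanel":
        """Panel restricted to the sites selected by a boolean mask/index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypePanel(
            self.subject_ids,
            tuple(self.site_ids[i] for i in idx),
            self.positions[idx],
            self.counts[:, idx],
        )

    def subset_subjects(self, mask) -> "GenotypePanel":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypePanel(
            tuple(self.subject_ids[i] for i in idx),
            self.site_ids,
            self.positions,
            self.counts[idx, :],
        )


@dataclass(frozen=True)
class PhenotypeVector:
    """Binary case/control labels (1 = case, 0 = control) aligned to a panel."""

    status: np.ndarray

    def __post_init__(self):
        st = np.asarray(self.status, dtype=np.int8)
        object.__setattr__(self, "status", st)
        if st.ndim != 1 or st.size < 2:
            raise ValueError("status must be a 1-D vector with at least 2 subjects")
        if not np.isin(st, (0, 1)).all():
            raise ValueError("status entries must be 0 (control) or 1 (case)")
        if st.sum() == 0 or st.sum() == st.size:
            raise ValueError("need at least one case and one control")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(self.status.size - self.status.sum())


def read_vcf(path, region=None) -> GenotypePanel:
    """Load a biallelic-SNV VCF into a :class:`GenotypePanel`.

    The minor allele is determined per site from the loaded sample (the allele
    with frequency <= 0.5; ties code the ALT allele as minor).  Multi-allelic
    and non-SNV records are skipped with a warning; subjects carrying any
    missing genotype in the region are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")
    rows, positions, site_ids = [], [], []
    chrom_seen = None
    # cyvcf2 gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dosage_map = np.array([0, 1, -1, 2], dtype=np.int8)
    it = vcf(region) if region else vcf
    for v in it:
        if chrom_seen is None:
            chrom_seen = v.CHROM
        elif v.CHROM != chrom_seen:
            raise ValueError("multi-chromosome VCF input; single-region analysis only")
        if len(v.ALT) != 1:
            logger.warning("skipping multi-allelic record at %s:%d", v.CHROM, v.POS)
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            logger.warning("skipping non-SNV record at %s:%d", v.CHROM, v.POS)
            continue
        if positions and v.POS <= positions[-1]:
            logger.warning("skipping duplicate/out-of-order position %s:%d", v.CHROM, v.POS)
            continue
        rows.append(dosage_map[np.asarray(v.gt_types)])
        positions.append(v.POS)
        site_ids.append(v.ID if v.ID and v.ID != "." else f"{v.CHROM}:{v.POS}")
    if not rows:
        raise ValueError(f"no biallelic SNV records loaded from {path}")
    alt = np.stack(rows, axis=1)  # subjects x sites
    keep = ~(alt < 0).any(axis=1)
    if not keep.all():
        dropped = [s for s, k in zip(samples, keep) if not k]
        logger.warning("dropping %d subject(s) with missing genotypes: %s",
                       len(dropped), ", ".join(dropped))
    if not keep.any():
        raise ValueError("all subjects dropped for missing genotypes")
    alt = alt[keep]
    samples = [s for s, k in zip(samples, keep) if k]
    alt_freq = alt.sum(axis=0) / (2.0 * alt.shape[0])
    flip = alt_freq > 0.5  # minor allele is REF at these sites
    counts = np.where(flip, 2 - alt, alt).astype(np.int8)
    return GenotypePanel(samples, site_ids, np.asarray(positions), counts)


def read_matrix(genotype_path, phenotype_path):
    """Read a subjects × sites count matrix and a phenotype table, aligned by subject id.

    The genotype file is tab-separated with subject ids in the first column and
    per-site base-pair positions as the remaining column headers; cells are
    minor-allele counts in {0,1,2}.  The phenotype file maps subject id to
    status in {0,1}.  Subjects present in only one file are dropped with a
    warning.

    Returns
    -------
    (GenotypePanel, PhenotypeVector)
    """
    geno = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
    try:
        positions = np.array([int(c) for c in geno.columns], dtype=np.int64)
    except ValueError as e:
        raise ValueError(f"genotype header columns must be integer positions: {e}") from e
    if positions.size > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("genotype column positions must be strictly increasing")
    vals = geno.to_numpy()
    try:
        cnt = vals.astype(np.int64)
    except ValueError:
        cnt = None
    if cnt is None or not np.isin(cnt, (0, 1, 2)).all():
        for i in range(vals.shape[0]):
            for j in range(vals.shape[1]):
                try:
                    ok = int(vals[i, j]) in (0, 1, 2)
                except ValueError:
                    ok = False
                if not ok:
                    raise ValueError(
                        f"invalid genotype cell {vals[i, j]!r} at subject "
                        f"{geno.index[i]!r}, position {geno.columns[j]!r}"
                    )
    pheno = pd.read_csv(phenotype_path, sep="\t", index_col=0)
    status_col = pheno.columns[0]
    pheno_map = pheno[status_col].to_dict()
    keep = [s for s in geno.index if s in pheno_map]
    dropped = sorted(set(geno.index).symmetric_difference(pheno.index))
    if dropped:
        logger.warning("dropping %d subject(s) present in only one file: %s",
                       len(dropped), ", ".join(map(str, dropped)))
    if not keep:
        raise ValueError("no subjects shared between genotype and phenotype files")
    panel = GenotypePanel(
        keep,
        tuple(geno.columns),
        positions,
        cnt[[geno.index.get_loc(s) for s in keep]],
    )
    status = np.array([pheno_map[s] for s in keep])
    return panel, PhenotypeVector(status)


def write_matrix(panel: GenotypePanel, path) -> None:
    """Write a panel in the tab-separated matrix format read by :func:`read_matrix`."""
    df = pd.DataFrame(
        panel.counts,
        index=pd.Index(panel.subject_ids, name="subject_id"),
        columns=[str(p) for p in panel.positions],
    )
    df.to_csv(path, sep="\t")


def write_phenotype(pheno: PhenotypeVector, subject_ids, path) -> None:
    df = pd.DataFrame(
        {"status": pheno.status},
        index=pd.Index(subject_ids, name="subject_id"),
    )
    df.to_csv(path, sep="\t")


def maf_filter(panel: GenotypePanel, pheno: PhenotypeVector | None = None,
               max_maf: float = 0.05) -> GenotypePanel:
    """Remove common and monomorphic sites.

    The minor-allele frequency is computed over all subjects (cases and
    controls pooled); sites with MAF > ``max_maf`` or MAF == 0 are removed,
    original site order is preserved.  Filtering is idempotent.
    """
    if pheno is not None and pheno.status.size != panel.n_subjects:
        raise ValueError("phenotype not aligned to panel")
    f = panel.counts.sum(axis=0) / (2.0 * panel.n_subjects)
    maf = np.minimum(f, 1.0 - f)
    keep = (maf > 0) & (maf <= max_maf)
    if not keep.any():
        raise NothingToTestError(
            f"no polymorphic site with MAF <= {max_maf}; nothing to test"
        )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("MAF filter removed %d of %d sites", n_removed, panel.n_sites)
    return panel.subset_sites(keep)
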