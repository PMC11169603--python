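"""Polygenic risk score (PRS) harmonization, scoring and standardization.

Weight files in PGS-catalog scoring format are aligned against the genotype
file's variants: strand-ambiguous (A/T, C/G) variants are removed, allele
pairs that disagree with the genotype file are dropped as discordant, and
weights are negated ("flipped") when the counted dosage allele is the weight
file's other allele.  Raw scores are PLINK-style sums of dosage x weight,
with missing dosages imputed at twice the counted-allele frequency, and are
reported alongside within-cohort z-scores so that odds ratios are per SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = ["PRSWeightSet", "GenotypeDosages", "read_pgs_weights", "read_vcf_dosages",
           "read_dosage_matrix", "harmonize", "score", "standardize",
           "prs_correlation_cluster"]


@dataclass
class PRSWeightSet:
    """One scoring file: per-variant effect allele, other allele and weight."""

    name: str
    table: pd.DataFrame  # columns: id, effect_allele, other_allele, weight

    def __post_init__(self) -> None:
        required = {"id", "effect_allele", "other_allele", "weight"}
        if not required <= set(self.table.columns):
            raise ValueError(f"weight table needs columns {sorted(required)}")
        if self.table["id"].duplicated().any():
            dups = self.table.loc[self.table["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids in {self.name}: {dups[:5]}")


@dataclass
class GenotypeDosages:
    """Dosage matrix of the counted allele (0-2; NaN = missing) plus the
    variant allele declarations."""

    samples: list[str]
    variants: pd.DataFrame  # columns: id, counted_allele, other_allele
    dosages: np.ndarray     # shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape does not match samples x variants")
        d = self.dosages
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ValueError("dosages must lie in [0, 2]")


_PGS_COLUMN_ALIASES = {
    "rsid": "id", "rsID": "id", "variant_id": "id", "ID": "id",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "reference_allele": "other_allele", "A1": "effect_allele", "A2": "other_allele",
    "effect_weight": "weight", "beta": "weight",
}


def read_pgs_weights(path, name: str | None = None) -> PRSWeightSet:
    """Read a PGS-catalog scoring file ('#' header lines, tab-separated
    rsID/effect_allele/other_allele/effect_weight columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df.rename(columns={c: _PGS_COLUMN_ALIASES.get(c, c) for c in df.columns})
    missing = {"id", "effect_allele", "other_allele", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["weight"] = df["weight"].astype(float)
    if name is None:
        name = str(path)
    return PRSWeightSet(name, df[["id", "effect_allele", "other_allele", "weight"]])


def read_vcf_dosages(path) -> GenotypeDosages:
    """Load dosages from a VCF.  Uses the DS FORMAT field when present,
    otherwise falls back to allele counts from hard genotype calls; the
    counted allele is ALT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, counted, other, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # biallelic SNVs only
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        counted.append(var.ALT[0])
        other.append(var.REF)
        try:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            ds = np.where(gt == 3, 2.0, gt)
            ds[gt == 2] = np.nan
        rows.append(ds)
    variants = pd.DataFrame({"id": ids, "counted_allele": counted, "other_allele": other})
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeDosages(samples, variants, dosages)


def read_dosage_matrix(path) -> GenotypeDosages:
    """Load a plain TSV dosage matrix: rows = samples (first column holds the
    sample id), columns named ``id_counted_other`` (e.g. ``rs1_A_G``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids, counted, other = [], [], []
    for col in df.columns:
        parts = col.rsplit("_", 2)
        if len(parts) != 3:
            raise ValueError(f"column {col!r} not in id_counted_other form")
        ids.append(parts[0])
        counted.append(parts[1])
        other.append(parts[2])
    variants = pd.DataFrame({"id": ids, "counted_allele": counted, "other_allele": other})
    return GenotypeDosages(list(df.index.astype(str)), variants, df.to_numpy(dtype=float))


def harmonize(weights: PRSWeightSet, variants: pd.DataFrame):
    """Align a weight set to the genotype variant table.

    Drops strand-ambiguous (A/T, C/G) and indel entries; drops weights whose
    allele pair does not match the genotype pair; negates the weight when the
    counted dosage allele is the weight file's *other* allele.  Returns the
    aligned table (id, weight, flipped) in genotype-variant order and a
    report counting {matched, flipped, ambiguous_dropped, discordant_dropped,
    missing, indel_dropped}.
    """
    report = {"matched": 0, "flipped": 0, "ambiguous_dropped": 0,
              "discordant_dropped": 0, "missing": 0, "indel_dropped": 0}
    geno = variants.set_index("id")
    rows = []
    for rec in weights.table.itertuples(index=False):
        ea, oa = str(rec.effect_allele).upper(), str(rec.other_allele).upper()
        if ea not in COMPLEMENT or oa not in COMPLEMENT:
            report["indel_dropped"] += 1
            continue
        if COMPLEMENT[ea] == oa:
            report["ambiguous_dropped"] += 1
            continue
        if rec.id not in geno.index:
            report["missing"] += 1
            continue
        g = geno.loc[rec.id]
        pair = {g["counted_allele"], g["other_allele"]}
        if {ea, oa} != pair:
            report["discordant_dropped"] += 1
            continue
        if g["counted_allele"] == ea:
            rows.append((rec.id, float(rec.weight), False))
            report["matched"] += 1
        else:
            rows.append((rec.id, -float(rec.weight), True))
            report["flipped"] += 1
    if not rows:
        raise ValueError(
            f"no variants shared between weight set {weights.name!r} and the genotype file"
        )
    aligned = pd.DataFrame(rows, columns=["id", "weight", "flipped"])
    return aligned, report


def score(dosages: GenotypeDosages, aligned: pd.DataFrame) -> pd.Series:
    """Raw PRS per participant: sum over variants of dosage x weight.

    Missing dosages are imputed as 2 x counted-allele frequency estimated
    from the non-missing dosages of that variant (mean dosage).  Aligned
    variants absent from the dosage matrix contribute 0.
    """
    pos = {v: i for i, v in enumerate(dosages.variants["id"])}
    total = np.zeros(len(dosages.samples))
    for rec in aligned.itertuples(index=False):
        j = pos.get(rec.id)
        if j is None:
            continue
        d = dosages.dosages[:, j].astype(float).copy()
        if np.isnan(d).any():
            fill = np.nanmean(d)
            d[np.isnan(d)] = 0.0 if np.isnan(fill) else fill
        total += d * rec.weight
    return pd.Series(total, index=dosages.samples, name="raw_score")


def standardize(raw) -> np.ndarray:
    """Within-cohort z-scores: (x - mean) / SD with the n-1 denominator."""
    x = np.asarray(raw, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 participants")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant score column is uninformative")
    return (x - x.mean()) / sd


def prs_correlation_cluster(profiles: pd.DataFrame):
    """Pearson correlation matrix across PRS columns plus Ward linkage on
    d = 1 - r; returns ``(corr, linkage)``."""
    import scipy.cluster.hierarchy as sch
    from scipy.spatial.distance import squareform

    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 scores")
    corr = profiles.corr()
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    linkage = sch.linkage(squareform(np.clip(dist, 0, None), checks=False), method="ward")
    return corr, linkage
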