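"""Cohort-level mutation landscape and association statistics.

The landscape is a gene x sample incidence matrix in which multi-hit
variants (several distinct variants of one gene in one sample) count as
multiple variants, so per-sample variant counts equal column sums.
Gene-frequency denominators are patients, not samples; longitudinal
pairs contribute one patient but two samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AnnotatedVariant
from .variant_io import infer_patient_id

log = logging.getLogger(__name__)

GENE_CATEGORIES = (
    "chromatin modification",
    "transcription factor",
    "RAS pathway",
    "receptor/kinase",
    "DNA repair/cell cycle",
    "splicing factor",
    "cohesin",
)


@dataclass
class CohortMatrix:
    """Gene x sample mutation-incidence matrix with multiplicities."""

    counts: pd.DataFrame  # genes as index, samples as columns
    sample_to_patient: dict[str, str]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def per_sample_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def patient_frequency(self) -> pd.Series:
        """Fraction of patients with >= 1 variant per gene."""
        patients = sorted(set(self.sample_to_patient.values()))
        by_patient = self.counts.T.groupby(
            self.counts.columns.map(self.sample_to_patient.get)
        ).any()
        return by_patient.reindex(patients, fill_value=False).mean(axis=0)

    def patient_gene_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {p: set() for p in set(self.sample_to_patient.values())}
        for sample in self.counts.columns:
            patient = self.sample_to_patient[sample]
            hit = self.counts.index[self.counts[sample] > 0]
            out[patient].update(hit)
        return out


def build_landscape(
    variants: Sequence[AnnotatedVariant],
    samples: Sequence[str],
    sample_to_patient: Optional[Mapping[str, str]] = None,
) -> CohortMatrix:
    """Tally distinct variants per gene per sample.

    Genes are ordered by descending patient frequency, ties broken
    alphabetically; a variant referencing an unknown sample is an error.
    """
    if sample_to_patient is None:
        sample_to_patient = {s: infer_patient_id(s) for s in samples}
    known = set(samples)
    cells: dict[tuple[str, str], set] = {}
    for av in variants:
        sample = av.call.sample_id
        if sample not in known:
            raise ValueError(f"variant references unknown sample {sample!r}")
        cells.setdefault((av.annotation.gene, sample), set()).add(av.call.key)
    genes = sorted({g for g, _ in cells})
    counts = pd.DataFrame(0, index=genes, columns=list(samples), dtype=int)
    for (gene, sample), keys in cells.items():
        counts.loc[gene, sample] = len(keys)
    matrix = CohortMatrix(counts=counts, sample_to_patient=dict(sample_to_patient))
    freq = matrix.patient_frequency()
    order = sorted(genes, key=lambda g: (-freq.get(g, 0.0), g))
    matrix.counts = counts.loc[order]
    return matrix


def categorize_genes(
    patient_genes: Mapping[str, Iterable[str]],
    category_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-patient boolean flags: does the patient carry >= 1 somatic
    variant in a gene of each functional category?

    Genes absent from the map are logged and counted under "other".
    """
    categories = list(GENE_CATEGORIES) + ["other"]
    rows = {}
    for patient, genes in patient_genes.items():
        flags = dict.fromkeys(categories, False)
        for gene in genes:
            cat = category_map.get(gene)
            if cat is None:
                log.warning("gene %s missing from category map; counted as 'other'", gene)
                cat = "other"
            elif cat not in categories:
                cat = "other"
            flags[cat] = True
        rows[patient] = flags
    return pd.DataFrame.from_dict(rows, orient="index", columns=categories).sort_index()


def pairwise_phi(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise phi coefficients (Pearson on 0/1 vectors) with p-values.

    p-values use the t transform with n-2 degrees of freedom.  Features
    with zero variance have undefined correlations and are reported NaN
    (diagonal entries are 1 whenever the feature varies).
    """
    n = len(features)
    if n < 3:
        raise ValueError("pairwise correlation needs >= 3 patients")
    cols = list(features.columns)
    phi = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    X = features.astype(float)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols[i:], start=i):
            xa, xb = X[a].to_numpy(), X[b].to_numpy()
            if xa.std() == 0 or xb.std() == 0:
                continue  # undefined
            if i == j:
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(xa, xb)
            phi.iloc[i, j] = phi.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return phi, pval


def chi_square_association(
    table: Sequence[Sequence[float]], yates: bool = False
) -> tuple[float, float]:
    """Chi-square test of association on a 2x2 table, optional Yates
    continuity correction; p from the 1-df upper tail."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() < 1:
        raise ValueError("empty table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total; association undefined")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact enumeration for combined n <= 20 without ties; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_cohort_frequencies(
    own: Mapping[str, float],
    others: Mapping[str, Mapping[str, float]],
    shared_genes: Sequence[str],
) -> pd.DataFrame:
    """Side-by-side gene variant frequencies (%) across cohorts.

    Returns one row per shared gene with each cohort's frequency, each
    cohort's descending rank, and the difference of every other cohort
    from the reference cohort.  A gene absent from a table is treated
    as 0% with a logged notice.
    """
    tables = {"own": own, **others}
    data = {}
    for name, table in tables.items():
        col = []
        for gene in shared_genes:
            if gene not in table:
                log.info("gene %s absent from cohort table %s; treated as 0%%", gene, name)
                col.append(0.0)
            else:
                col.append(float(table[gene]))
        data[f"freq_{name}"] = col
    df = pd.DataFrame(data, index=list(shared_genes))
    for name in tables:
        df[f"rank_{name}"] = (
            df[f"freq_{name}"].rank(ascending=False, method="min").astype(int)
        )
    for name in others:
        df[f"diff_{name}"] = df[f"freq_{name}"] - df["freq_own"]
    return df.sort_values("rank_own", kind="mergesort")


def progression_changes(
    initial: Sequence[AnnotatedVariant], progression: Sequence[AnnotatedVariant]
) -> dict[str, list]:
    """Gained/lost variant keys between a patient's initial and
    progression samples (positive/negative clonal selection)."""
    before = {av.call.key: av for av in initial}
    after = {av.call.key: av for av in progression}
    return {
        "gained": sorted(set(after) - set(before)),
        "lost": sorted(set(before) - set(after)),
        "persistent": sorted(set(before) & set(after)),
    }


def write_landscape(matrix: CohortMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")
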