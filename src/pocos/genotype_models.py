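"""Adaptive binarization of genotypes under five candidate models.

Each biallelic locus admits five binary encodings of its genotype, defined
by the set of genotype states treated as the "genotype of interest"
(``a`` = minor allele, ``A`` = major allele):

1. homozygous minor      {aa}
2. heterozygous          {Aa}
3. homozygous major      {AA}
4. minor-allele presence {Aa, aa}   (complement of 3)
5. major-allele presence {Aa, AA}   (complement of 1)

For each model the discrimination score D is the difference between the
fraction of cases and the fraction of controls carrying the genotype of
interest; the model with the largest |D| is selected per locus. Because
models 4/5 are complements of 3/1, |D| ties structurally whenever no
genotype is missing; ties are resolved toward models with D > 0 (a
1-profile enriched in cases is what set coverage consumes), then toward the
lowest model index. Missing genotypes contribute 0 to every profile while
the case/control denominators stay at the full class sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import UndefinedTestError
from .gwas_io import MISSING, GwasDataset

#: genotype-of-interest sets in minor-allele-count space, per model (1..5)
MODEL_GENOTYPES = {
    1: (2,),
    2: (1,),
    3: (0,),
    4: (1, 2),
    5: (0, 1),
}

#: boolean lookup: _MODEL_TABLE[model-1, minor_count] == genotype of interest
_MODEL_TABLE = np.zeros((5, 3), dtype=bool)
for _m, _gs in MODEL_GENOTYPES.items():
    for _g in _gs:
        _MODEL_TABLE[_m - 1, _g] = True

_TIE_TOL = 1e-12  # complement pairs differ only by float rounding


@dataclass
class BinaryProfileSet:
    """Per-locus model scores, selected models, and the binary matrix M.

    ``interest_allele2`` stores each locus's selected genotype-of-interest
    set as a boolean lookup over allele2 copy counts, so the selection
    learned on one sample subset can be applied verbatim to held-out
    samples of the same cohort.
    """

    locus_ids: list[str]
    D: np.ndarray  # (n_loci, 5)
    model_index: np.ndarray  # (n_loci,), values 1..5
    interest_allele2: np.ndarray  # (n_loci, 3) bool
    M: np.ndarray  # (n_loci, n_samples) bool, on the training samples

    def binarize_dataset(self, dataset: GwasDataset) -> np.ndarray:
        """Binary matrix for ``dataset`` under the selected models.

        Loci are matched by position in ``locus_ids`` (the dataset must
        carry the same loci in the same order). Missing genotypes map to 0.
        """
        if dataset.locus_ids != self.locus_ids:
            raise KeyError("dataset loci do not match the fitted profile set")
        g = dataset.genotypes
        safe = np.clip(g, 0, 2)
        out = np.take_along_axis(self.interest_allele2, safe.astype(np.intp), axis=1)
        out[g == MISSING] = False
        return out

    def to_frame(self):
        """Audit table: locus id, selected model, and the five D scores."""
        import pandas as pd

        df = pd.DataFrame(self.D, columns=[f"D{i}" for i in range(1, 6)])
        df.insert(0, "locus_id", self.locus_ids)
        df.insert(1, "model", self.model_index)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def binarize(dataset: GwasDataset, locus_id: str, model_index: int) -> np.ndarray:
    """Binary profile of one locus under one of the five genotype models."""
    if model_index not in MODEL_GENOTYPES:
        raise ValueError("model_index must be in 1..5")
    mc = dataset.minor_counts[dataset._idx(locus_id)]
    profile = np.zeros(dataset.n_samples, dtype=bool)
    obs = mc != MISSING
    profile[obs] = _MODEL_TABLE[model_index - 1, mc[obs]]
    return profile


def coverage_difference(profile: np.ndarray, phenotype: np.ndarray) -> float:
    """D = <f, m>/|S1| - <1-f, m>/|S0| for a binary profile m."""
    phenotype = np.asarray(phenotype)
    profile = np.asarray(profile, dtype=float)
    n1 = int((phenotype == 1).sum())
    n0 = int((phenotype == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedTestError("coverage difference needs both phenotype classes")
    return float(profile[phenotype == 1].sum() / n1 - profile[phenotype == 0].sum() / n0)


def _select(D: np.ndarray) -> np.ndarray:
    """Vectorized model choice: max |D|, ties -> D > 0, then lowest index."""
    absD = np.abs(D)
    max_abs = absD.max(axis=1, keepdims=True)
    tied = absD >= max_abs - _TIE_TOL
    positive = tied & (D > _TIE_TOL)
    # prefer a positive-D model when one attains the maximum
    pool = np.where(positive.any(axis=1, keepdims=True), positive, tied)
    return pool.argmax(axis=1) + 1  # argmax returns the lowest True index


def select_models(dataset: GwasDataset) -> BinaryProfileSet:
    """Score all five models at every locus and select one per locus."""
    n1, n0 = dataset.n_cases, dataset.n_controls
    if n1 == 0 or n0 == 0:
        raise UndefinedTestError("model selection needs both phenotype classes")
    mc = dataset.minor_counts
    case = dataset.case_mask

    # per-locus counts of each genotype state in cases / controls
    counts1 = np.stack([((mc == g) & case).sum(axis=1) for g in range(3)], axis=1)
    counts0 = np.stack([((mc == g) & ~case).sum(axis=1) for g in range(3)], axis=1)
    # model coverage counts: (n_loci, 5)
    cov1 = counts1 @ _MODEL_TABLE.T
    cov0 = counts0 @ _MODEL_TABLE.T
    D = cov1 / n1 - cov0 / n0
    k = _select(D)

    interest_minor = _MODEL_TABLE[k - 1]  # (n_loci, 3) in minor-count space
    interest_allele2 = np.where(
        dataset.minor_is_allele2[:, None], interest_minor, interest_minor[:, ::-1]
    )
    profiles = BinaryProfileSet(
        locus_ids=list(dataset.locus_ids),
        D=D,
        model_index=k.astype(np.int64),
        interest_allele2=interest_allele2,
        M=np.empty((0, 0), dtype=bool),
    )
    profiles.M = profiles.binarize_dataset(dataset)
    return profiles


def select_model(dataset: GwasDataset, locus_id: str) -> tuple[int, np.ndarray]:
    """Selected model index and binary profile for a single locus."""
    profiles = select_models(dataset)
    i = dataset._idx(locus_id)
    return int(profiles.model_index[i]), profiles.M[i]
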