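"""Post-hoc population genetics and phenotype analysis.

Morph classification groups the evolved (alpha, delta, rho) phenotypes
into discrete movement types by single-linkage clustering, cut at a gap
threshold on the scale of the late-epoch mutation noise.  The
Hardy-Weinberg machinery estimates allele frequencies from unordered
genotype counts, computes the expected genotype counts p_i^2 N and
2 p_i p_j N under random mating, and tests goodness of fit with a
chi-square whose degrees of freedom are (#genotype classes - #alleles),
accounting for the frequencies estimated from the same sample.

Allele identity in simulation output is tracked by lineage tag (descent),
so these analyses never depend on numeric rounding; :func:`bin_alleles`
is provided only for value-only snapshots such as externally tabulated snapshots.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2 as chi2_dist

from .evolution import EpochResult, Ploidy
from .foraging import Agent

__all__ = [
    "HWResult",
    "classify_morphs",
    "allele_frequencies",
    "hw_expected_counts",
    "summarize_parameter_trajectory",
    "genotype_counts",
    "bin_alleles",
]

_TRAITS = ("alpha", "delta", "rho")


@dataclass
class HWResult:
    """Hardy-Weinberg analysis of a sample of diploid genotype counts."""

    alleles: list
    allele_counts: dict
    frequencies: dict
    observed: dict       # unordered genotype -> observed count
    expected: dict       # unordered genotype -> HW expected count
    chi2: float
    df: int
    p_value: float


def _norm_genotype(g) -> tuple:
    a, b = g
    return (a, b) if str(a) <= str(b) else (b, a)


def allele_frequencies(genotype_counts: Mapping) -> dict:
    """Allele frequencies from unordered diploid genotype counts.

    freq(i) = (2 n_ii + sum_{j != i} n_ij) / (2 N); frequencies sum to 1.
    """
    counts = {_norm_genotype(g): c for g, c in genotype_counts.items()}
    if any(c < 0 for c in counts.values()):
        raise ValueError("genotype counts must be >= 0")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("need at least one observed genotype")
    copies: dict = {}
    for (a, b), c in counts.items():
        copies[a] = copies.get(a, 0) + c
        copies[b] = copies.get(b, 0) + c
    denom = 2 * total
    return {a: n / denom for a, n in copies.items()}


def hw_expected_counts(genotype_counts: Mapping) -> HWResult:
    """Expected genotype counts under Hardy-Weinberg plus chi-square fit.

    Expected homozygote ii: N p_i^2; heterozygote ij: 2 N p_i p_j, over
    every genotype constructible from the observed alleles (unobserved
    classes enter with observed count 0).  Classes with expected count 0
    are excluded from the chi-square sum; df = #classes - #alleles.
    """
    observed = {}
    for g, c in genotype_counts.items():
        key = _norm_genotype(g)
        observed[key] = observed.get(key, 0) + c
    freqs = allele_frequencies(observed)
    alleles = sorted(freqs, key=str)
    N = sum(observed.values())

    expected = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            if a == b:
                expected[(a, b)] = N * freqs[a] ** 2
            else:
                expected[_norm_genotype((a, b))] = 2 * N * freqs[a] * freqs[b]

    chi2 = 0.0
    used = 0
    for g, e in expected.items():
        if e > 0:
            o = observed.get(g, 0)
            chi2 += (o - e) ** 2 / e
            used += 1
    df = used - len(alleles)
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else float("nan")

    copies = {a: freqs[a] * 2 * N for a in alleles}
    full_observed = {g: observed.get(g, 0) for g in expected}
    return HWResult(
        alleles=alleles,
        allele_counts=copies,
        frequencies=freqs,
        observed=full_observed,
        expected=expected,
        chi2=float(chi2),
        df=df,
        p_value=p,
    )


def classify_morphs(
    phenotypes,
    gap_threshold: float = 0.03,
    fitness=None,
    traits: tuple[str, ...] = _TRAITS,
) -> pd.DataFrame:
    """Group phenotypes into discrete morphs (movement types).

    Single-linkage agglomerative clustering in trait space, cut at
    ``gap_threshold``: two phenotypes belong to the same morph when they
    are connected by a chain of steps each shorter than the threshold.
    The default 0.03 is on the scale of late-epoch mutation noise, so
    within-morph mutational scatter stays merged while evolved gaps
    between types split.

    ``traits`` selects which of (alpha, delta, rho) the clustering
    metric uses (summaries always cover all three).  Returns one row per
    morph, sorted by mean alpha, with member counts summing to the
    population size.
    """
    X = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if X.size == 0:
        raise ValueError("empty phenotype list")
    if X.shape[1] != 3:
        raise ValueError("phenotypes must be (n, 3): alpha, delta, rho")
    n = X.shape[0]
    idx = [_TRAITS.index(t) for t in traits]
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(X[:, idx], method="single")
        labels = fcluster(Z, t=gap_threshold, criterion="distance")

    fit = np.asarray(fitness, dtype=float) if fitness is not None else None
    rows = []
    for lab in np.unique(labels):
        mask = labels == lab
        row = {"count": int(mask.sum())}
        for j, t in enumerate(_TRAITS):
            row[f"{t}_mean"] = float(X[mask, j].mean())
            row[f"{t}_sd"] = float(X[mask, j].std())
        if fit is not None:
            row["fitness_mean"] = float(fit[mask].mean())
            row["fitness_sd"] = float(fit[mask].std())
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("alpha_mean", ignore_index=True)
    out.insert(0, "morph", np.arange(1, len(out) + 1))
    return out


def summarize_parameter_trajectory(epoch: EpochResult, trait: str) -> pd.DataFrame:
    """Per-generation population mean and SD of one expressed trait."""
    if trait not in _TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {_TRAITS}")
    return pd.DataFrame(
        {
            "generation": [r.generation for r in epoch.records],
            "mean": [r.trait_mean[trait] for r in epoch.records],
            "sd": [r.trait_sd[trait] for r in epoch.records],
        }
    )


def genotype_counts(agents: list[Agent], trait: str) -> dict:
    """Unordered genotype counts for one trait, keyed by allele lineage tag."""
    if trait not in _TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {_TRAITS}")
    t = _TRAITS.index(trait)
    counts: dict = {}
    for a in agents:
        g = a.genotype
        if g is None or g.ploidy is not Ploidy.DIPLOID:
            raise TypeError("genotype_counts requires diploid agents")
        key = _norm_genotype((int(g.tags[t, 0]), int(g.tags[t, 1])))
        counts[key] = counts.get(key, 0) + 1
    return counts


def bin_alleles(values, tol: float = 0.02) -> np.ndarray:
    """Assign integer allele labels to numeric allele values by gap binning.

    Values closer than ``tol`` to their sorted neighbour share a label.
    Only for value-only snapshots where lineage tags are unavailable.
    """
    v = np.asarray(values, dtype=float).ravel()
    order = np.argsort(v)
    labels = np.empty(v.shape, dtype=np.int64)
    current = 0
    prev = None
    for i in order:
        if prev is not None and v[i] - prev > tol:
            current += 1
        labels[i] = current
        prev = v[i]
    return labels
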