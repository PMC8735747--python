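"""Hardy-Weinberg equilibrium testing and the control-group inclusion filter.

Under random mating a biallelic locus with mutant-allele frequency q has
genotype proportions ((1-q)^2, 2q(1-q), q^2). Departure from these
proportions in *controls* is the standard genotyping-quality screen for a
case-control study, and studies whose controls fail it are excluded from
meta-analysis.

The default test is the Pearson chi-square on the three genotype cells with
1 degree of freedom (one parameter, q, is estimated) and no continuity
correction. An exact test (conditional on allele counts) is available as an
alternative for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .dataset import GenotypeCounts, StudyTable
from .errors import MonomorphicMarkerError
from .models import allele_frequency

__all__ = ["HweResult", "hwe_chi_square", "hwe_exact", "hwe_filter"]


@dataclass(frozen=True)
class HweResult:
    """Result of a Hardy-Weinberg test on one group's genotype counts."""

    chi2: float
    df: int
    p: float
    q: float  # estimated mutant-allele frequency
    method: str = "chi2"


def hwe_chi_square(controls: GenotypeCounts) -> HweResult:
    """Pearson chi-square HWE test, 1 df, no continuity correction.

    Raises
    ------
    MonomorphicMarkerError
        If the group carries only one allele (q = 0 or 1); the test is
        undefined rather than trivially passing.
    """
    q = allele_frequency(controls)
    if q == 0.0 or q == 1.0:
        raise MonomorphicMarkerError(
            f"marker monomorphic in this group (q = {q}); HWE test undefined"
        )
    n = controls.n
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2)
    observed = (controls.cc, controls.ct, controls.tt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=float(chi2), df=1, p=p, q=q)


def hwe_exact(controls: GenotypeCounts) -> HweResult:
    """Exact HWE test: sum of conditional heterozygote-count probabilities.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one (the
    "SNP-HWE" convention). Provided as a small-sample alternative; the
    chi-square test is the package default.
    """
    q = allele_frequency(controls)
    if q == 0.0 or q == 1.0:
        raise MonomorphicMarkerError(
            f"marker monomorphic in this group (q = {q}); HWE test undefined"
        )
    n = controls.n
    n_t = controls.ct + 2 * controls.tt  # rarity is irrelevant; condition on T count
    # log-probability of each compatible heterozygote count, up to a constant
    het_min = n_t % 2
    hets = range(het_min, min(n_t, 2 * n - n_t) + 1, 2)
    logps = {}
    for h in hets:
        tt = (n_t - h) // 2
        cc = n - h - tt
        logps[h] = (
            math.lgamma(n + 1)
            - math.lgamma(cc + 1)
            - math.lgamma(h + 1)
            - math.lgamma(tt + 1)
            + h * math.log(2)
        )
    mx = max(logps.values())
    probs = {h: math.exp(lp - mx) for h, lp in logps.items()}
    total = sum(probs.values())
    obs = probs[controls.ct]
    p = min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total)
    chi = hwe_chi_square(controls)
    return HweResult(chi2=chi.chi2, df=1, p=p, q=q, method="exact")


def hwe_filter(
    table: StudyTable, alpha: float = 0.01, exact: bool = False
) -> tuple[StudyTable, list[tuple[str, HweResult]]]:
    """Split a study table on the HWE inclusion rule (exclude if p < alpha).

    A study is retained when its control-group HWE p-value is >= ``alpha``
    (exclusion is strict: p exactly equal to alpha is retained). Returns the
    retained table and a list of (study_id, HweResult) for exclusions.
    """
    test = hwe_exact if exact else hwe_chi_square
    retained = []
    excluded: list[tuple[str, HweResult]] = []
    for study in table:
        result = test(study.controls)
        if result.p < alpha:
            excluded.append((study.study_id, result))
        else:
            retained.append(study)
    return (
        StudyTable(studies=tuple(retained), provenance=table.provenance),
        excluded,
    )
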