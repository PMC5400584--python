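"""Chi-square enrichment of mutation burden in domain families.

"Mutational frequency" is operationalised as mutations per
residue-opportunity: a family's exposure is the summed length of its
instances times the number of samples, which jointly normalises for
domain frequency, domain length and cohort size. Each family is tested
with a 2x2 Pearson chi-square (no continuity correction, 1 df) of
observed/remaining opportunities against a pooled background — either a
fixed panel of cancer-unrelated families (cancer-gene mode) or all other
families (genome-wide mode). Classes are tested independently and
Bonferroni-corrected by the number of families tested; a family is
called enriched only when its rate also exceeds the background rate, so
depleted families are never flagged.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger("domainspot")


@dataclass(frozen=True)
class EnrichmentResult:
    family_id: str
    mclass: str
    observed_mutations: int
    exposure: int
    background_mutations: int
    background_exposure: int
    chi2_stat: float
    p_value: float
    p_corrected: float
    enriched: bool

    @property
    def rate_ratio(self) -> float:
        """Observed over background mutation rate (inf if background is 0)."""
        obs = self.observed_mutations / self.exposure
        bg = self.background_mutations / self.background_exposure
        return obs / bg if bg > 0 else float("inf")


def compute_exposure(instances, n_samples: int) -> int:
    """Mutation opportunities of a family: sum of instance lengths x samples."""
    if not instances:
        raise ValueError("empty family has no exposure")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return sum(inst.length for inst in instances) * n_samples


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Pearson chi-square on [[a, b], [c, d]] without continuity correction.

    Closed form N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p from chi2(1).
    A zero marginal makes the test undefined and returns (0.0, 1.0) with
    a log entry.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        logger.debug("degenerate 2x2 table [[%d,%d],[%d,%d]]", a, b, c, d)
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return stat, float(chi2.sf(stat, df=1))


def _count_by_family(mapped, mclass: str) -> dict:
    counts = defaultdict(int)
    for m in mapped:
        if m.mclass == mclass:
            counts[m.family_id] += 1
    return counts


def _test_families(tested: dict, bg_obs: int, bg_expo: int, mclass: str,
                   alpha: float) -> list:
    """Run the 2x2 test per family against one pooled background."""
    m = len(tested)
    results = []
    for family_id in sorted(tested):
        obs, expo = tested[family_id]
        if obs > expo:
            raise ValueError(
                f"family {family_id!r}: observed {obs} exceeds exposure {expo} "
                "(mapping bug)"
            )
        stat, p = chi_square_2x2(obs, expo - obs, bg_obs, bg_expo - bg_obs)
        p_corr = min(1.0, p * m)
        rate_up = bg_expo > 0 and obs * bg_expo > bg_obs * expo
        results.append(EnrichmentResult(
            family_id, mclass, obs, expo, bg_obs, bg_expo,
            stat, p, p_corr, enriched=bool(p_corr < alpha and rate_up),
        ))
    return results


def enrich_against_background(families: dict, background_families: dict,
                              mapped, mclass: str, n_samples: int,
                              alpha: float = 0.05) -> list:
    """Test each family against a pooled panel of background families.

    ``families`` and ``background_families`` map family id to instance
    list and must be disjoint. The background panel is pooled into a
    single row of the 2x2 table; Bonferroni m is the number of tested
    families.
    """
    shared = set(families) & set(background_families)
    if shared:
        raise ValueError(f"background overlaps tested families: {sorted(shared)}")
    counts = _count_by_family(mapped, mclass)
    tested = {
        fam: (counts.get(fam, 0), compute_exposure(insts, n_samples))
        for fam, insts in families.items()
    }
    bg_obs = sum(counts.get(fam, 0) for fam in background_families)
    bg_expo = sum(compute_exposure(insts, n_samples)
                  for insts in background_families.values())
    return _test_families(tested, bg_obs, bg_expo, mclass, alpha)


def enrich_genome_wide(families: dict, mapped, mclass: str, n_samples: int,
                       alpha: float = 0.05) -> list:
    """Test each family against all other families pooled.

    Identical contract to :func:`enrich_against_background` except the
    background for family F is every family but F; requires >= 2 families.
    """
    if len(families) < 2:
        raise ValueError("genome-wide enrichment needs at least 2 families")
    counts = _count_by_family(mapped, mclass)
    exposures = {fam: compute_exposure(insts, n_samples)
                 for fam, insts in families.items()}
    total_obs = sum(counts.get(fam, 0) for fam in families)
    total_expo = sum(exposures.values())
    m = len(families)
    results = []
    for family_id in sorted(families):
        obs, expo = counts.get(family_id, 0), exposures[family_id]
        if obs > expo:
            raise ValueError(
                f"family {family_id!r}: observed {obs} exceeds exposure {expo}"
            )
        bg_obs, bg_expo = total_obs - obs, total_expo - expo
        stat, p = chi_square_2x2(obs, expo - obs, bg_obs, bg_expo - bg_obs)
        p_corr = min(1.0, p * m)
        rate_up = bg_expo > 0 and obs * bg_expo > bg_obs * expo
        results.append(EnrichmentResult(
            family_id, mclass, obs, expo, bg_obs, bg_expo,
            stat, p, p_corr, enriched=bool(p_corr < alpha and rate_up),
        ))
    return results


def enrichment_frame(results) -> pd.DataFrame:
    """Deterministic result table (one analysis/class per file)."""
    columns = ["family", "mclass", "observed", "exposure", "bg_observed",
               "bg_exposure", "rate_ratio", "chi2_stat", "p_value",
               "p_corrected", "enriched"]
    rows = [
        [r.family_id, r.mclass, r.observed_mutations, r.exposure,
         r.background_mutations, r.background_exposure, r.rate_ratio,
         r.chi2_stat, r.p_value, r.p_corrected, r.enriched]
        for r in sorted(results, key=lambda r: (r.p_value, r.family_id))
    ]
    return pd.DataFrame(rows, columns=columns)
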