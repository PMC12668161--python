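"""Gene dosage-response classification and deletion/duplication comparisons.

Deletions and duplications push gene dosage in opposite directions, so a
*monotonic* dosage response is one where their effect sizes on a trait
have opposite signs. Each (gene set, trait) pair with at least one
FDR-significant association is classified by sign (monotonic vs
non-monotonic) and by evidence: *truly* monotonic/non-monotonic when both
dosage types are significant, otherwise undetermined on the
non-significant side. Per-trait deletion–duplication effect-size
correlations use the overlap-conditioned permutation p-value, and the
overlap between CNV-associated gene sets and an external reference list
(e.g. common-variant enrichments) is tested by permuting the CNV side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from .normative import group_difference
from .pjaccard import PermutationNull, _empirical_p
from .correlation import rg_pjaccard

__all__ = [
    "DosageResponse",
    "OverlapTest",
    "classify_responses",
    "deldup_effect_correlation",
    "monotonic_fraction_by_group",
    "functional_overlap_test",
]


@dataclass
class DosageResponse:
    gene_set: str
    trait: str
    del_beta: float
    del_q: float
    dup_beta: float
    dup_q: float
    sign_class: Optional[str]  # monotonic | non-monotonic | None (null)
    evidence_class: str  # truly_* | undetermined_del | undetermined_dup | null


def classify_responses(
    grid: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Classify every (gene set, trait) dosage response from the grid.

    ``null`` when neither dosage type is significant; otherwise the sign
    class is monotonic when del_beta·dup_beta < 0 and non-monotonic when
    ≥ 0 (a degenerate zero product counts as non-monotonic), and the
    evidence class records which side carries the significance.
    """
    wide = grid.pivot_table(
        index=["gene_set", "trait"],
        columns="dosage_type",
        values=["beta", "q"],
        aggfunc="first",
    )
    if ("beta", "DEL") not in wide.columns or ("beta", "DUP") not in wide.columns:
        raise ValueError("grid must contain both DEL and DUP cells")
    if wide[("beta", "DEL")].isna().any() or wide[("beta", "DUP")].isna().any():
        raise ValueError("grid is not rectangular over dosage types")
    rows = []
    for (gene_set, trait), row in wide.iterrows():
        del_beta, dup_beta = row[("beta", "DEL")], row[("beta", "DUP")]
        del_q, dup_q = row[("q", "DEL")], row[("q", "DUP")]
        del_sig = del_q < q_threshold
        dup_sig = dup_q < q_threshold
        if not del_sig and not dup_sig:
            sign_class, evidence = None, "null"
        else:
            sign_class = "monotonic" if del_beta * dup_beta < 0 else "non-monotonic"
            if del_sig and dup_sig:
                evidence = (
                    "truly_monotonic"
                    if sign_class == "monotonic"
                    else "truly_non_monotonic"
                )
            elif del_sig:
                evidence = "undetermined_del"  # only the deletion side is significant
            else:
                evidence = "undetermined_dup"
        rows.append(
            {
                "gene_set": gene_set,
                "trait": trait,
                "del_beta": del_beta,
                "del_q": del_q,
                "dup_beta": dup_beta,
                "dup_q": dup_q,
                "sign_class": sign_class,
                "evidence_class": evidence,
            }
        )
    return pd.DataFrame(rows)


def deldup_effect_correlation(
    grid: pd.DataFrame,
    trait: str,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> Tuple[float, PermutationNull]:
    """Pearson r between deletion and duplication effect-size profiles of
    one trait across gene sets, with an overlap-conditioned p-value."""
    sub = grid[grid["trait"] == trait]
    del_prof = sub[sub["dosage_type"] == "DEL"].set_index("gene_set")["beta"]
    dup_prof = sub[sub["dosage_type"] == "DUP"].set_index("gene_set")["beta"]
    dup_prof = dup_prof.reindex(del_prof.index)
    if del_prof.std() == 0 or dup_prof.std() == 0:
        raise ValueError(f"constant effect profile for trait {trait!r}")
    r = float(np.corrcoef(del_prof.to_numpy(), dup_prof.to_numpy())[0, 1])
    null = rg_pjaccard(del_prof, dup_prof, collection, n_perm=n_perm, seed=seed)
    return r, null


def monotonic_fraction_by_group(
    responses: pd.DataFrame, trait_groups: Dict[str, str]
) -> Tuple[pd.DataFrame, float]:
    """Per-trait monotonic share among non-null responses, plus a rank-sum
    p-value comparing the two trait groups (e.g. brain vs non-brain).

    Traits with zero non-null responses are excluded with a warning row
    omitted rather than a zero.
    """
    non_null = responses[responses["evidence_class"] != "null"]
    rows = []
    for trait, sub in non_null.groupby("trait"):
        frac = float((sub["sign_class"] == "monotonic").mean())
        rows.append(
            {
                "trait": trait,
                "group": trait_groups.get(trait, "unknown"),
                "n_responses": len(sub),
                "monotonic_fraction": frac,
            }
        )
    table = pd.DataFrame(
        rows, columns=["trait", "group", "n_responses", "monotonic_fraction"]
    )
    groups = [g for g in table["group"].unique() if g != "unknown"]
    p = np.nan
    if len(groups) == 2:
        a = table.loc[table["group"] == groups[0], "monotonic_fraction"]
        b = table.loc[table["group"] == groups[1], "monotonic_fraction"]
        if len(a) and len(b):
            p = group_difference(a, b)
    return table, p


@dataclass
class OverlapTest:
    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    reference_sets: Tuple[str, ...]


def functional_overlap_test(
    cnv_significant_sets: Sequence[str],
    reference_enriched_sets: Sequence[str],
    universe_sets: Sequence[str],
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> OverlapTest:
    """Test whether CNV-associated gene sets overlap a fixed reference list
    more than chance.

    Observed overlap = |intersection| / |cnv_significant_sets|. Each null
    replicate redraws the CNV side uniformly without replacement from the
    gene-set universe, keeping the reference side fixed; p is one-sided
    for greater overlap.
    """
    cnv_sets = list(dict.fromkeys(cnv_significant_sets))
    if not cnv_sets:
        raise ValueError("empty CNV-significant set list")
    universe = list(dict.fromkeys(universe_sets))
    missing = (set(cnv_sets) | set(reference_enriched_sets)) - set(universe)
    if missing:
        raise ValueError(f"sets outside the universe: {sorted(missing)[:5]}")
    reference = frozenset(reference_enriched_sets)
    k = len(cnv_sets)
    observed = len(reference.intersection(cnv_sets)) / k
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    uni = np.array(universe, dtype=object)
    for r in range(n_perm):
        draw = rng.choice(uni, size=k, replace=False)
        null[r] = len(reference.intersection(draw)) / k
    p = _empirical_p(observed, null, two_sided=False)
    return OverlapTest(observed, null, p, n_perm, tuple(reference_enriched_sets))
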