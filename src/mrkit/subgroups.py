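"""Category-driven sensitivity analyses.

The exposure GWAS's instruments carry curated biological-category labels
(a SNP may belong to several).  Three checks probe whether the causal
estimate is driven by particular biology: a neuronal vs non-neuronal
split, IVW re-estimation leaving one category out at a time, and full
re-estimation after removing forward-selected heterogeneity-driving
categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .estimators import (MRResult, SimexConfig, ivw, mr_egger, simex_egger,
                         weighted_median)
from .summary_io import HarmonizedInstrument

logger = logging.getLogger("mrkit")

#: The four neuronal-related category labels.
NEURONAL_LABELS = (
    "Neuronal developmental processes",
    "Neurotransmission",
    "Hypothalamic expression and regulatory function",
    "Neuronal expression",
)


@dataclass
class CategoryScheme:
    """Mapping from biological-category label to the set of member SNP ids."""

    members: dict[str, set[str]] = field(default_factory=dict)
    neuronal_labels: tuple[str, ...] = NEURONAL_LABELS

    def categories_of(self, snp_id: str) -> set[str]:
        return {c for c, snps in self.members.items() if snp_id in snps}

    def labels(self) -> list[str]:
        return sorted(self.members)

    def validate_against(self, instruments: Sequence[HarmonizedInstrument]) -> None:
        known = {i.snp_id for i in instruments} | {i.proxy_of for i in instruments}
        stray = {s for snps in self.members.values() for s in snps} - known
        if stray:
            raise ValueError(
                f"category scheme references SNPs absent from the harmonized "
                f"dataset: {', '.join(sorted(stray)[:10])}")

    def restrict(self, min_size: int) -> "CategoryScheme":
        """Keep only categories with at least ``min_size`` member SNPs."""
        return CategoryScheme(
            members={c: set(s) for c, s in self.members.items() if len(s) >= min_size},
            neuronal_labels=self.neuronal_labels)

    def indicator_frame(self, instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
        """0/1 membership matrix, one row per instrument, one column per label.

        Membership is looked up under the instrument's own id and, for
        proxied instruments, under the index SNP's id.
        """
        rows = {
            lab: [int(_member(i, snps)) for i in instruments]
            for lab, snps in sorted(self.members.items())
        }
        return pd.DataFrame(rows)

    @classmethod
    def from_table(cls, path, neuronal_labels: tuple[str, ...] = NEURONAL_LABELS
                   ) -> "CategoryScheme":
        """Read a long-format tab-delimited (snp_id, category) table."""
        df = pd.read_csv(path, sep="\t")
        if not {"snp_id", "category"} <= set(df.columns):
            raise ValueError("category scheme table needs columns snp_id, category")
        members: dict[str, set[str]] = {}
        for r in df.itertuples(index=False):
            members.setdefault(str(r.category), set()).add(str(r.snp_id))
        return cls(members=members, neuronal_labels=neuronal_labels)


def _member(instr: HarmonizedInstrument, snps: set[str]) -> bool:
    return instr.snp_id in snps or (bool(instr.proxy_of) and instr.proxy_of in snps)


def split_neuronal(instruments: Sequence[HarmonizedInstrument],
                   scheme: CategoryScheme):
    """Split instruments into neuronal-related and non-neuronal subsets.

    A SNP is neuronal if it belongs to any of the scheme's neuronal
    labels; everything else — including uncategorized SNPs, which are
    warned about — goes to the "other" subset.  The subsets are disjoint
    and jointly exhaustive.
    """
    neuronal_snps: set[str] = set()
    for lab in scheme.neuronal_labels:
        neuronal_snps |= scheme.members.get(lab, set())
    all_categorized = {s for snps in scheme.members.values() for s in snps}
    neuronal, other = [], []
    uncategorized = []
    for i in instruments:
        if _member(i, neuronal_snps):
            neuronal.append(i)
        else:
            other.append(i)
            if not _member(i, all_categorized):
                uncategorized.append(i.snp_id)
    if uncategorized:
        logger.warning("split_neuronal: %d uncategorized SNP(s) assigned to "
                       "'other': %s", len(uncategorized), ", ".join(uncategorized))
    return neuronal, other


def _result_row(res: Optional[MRResult], **extra) -> dict:
    row = dict(extra)
    if res is None:
        row.update({"n_snps": extra.get("n_snps"), "computed": False})
        return row
    row.update({
        "method": res.method, "n_snps": res.n_snps, "computed": True,
        "estimate_logor": res.estimate, "se": res.se,
        "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
        "or": res.or_, "or_ci_low": res.or_ci[0], "or_ci_high": res.or_ci[1],
    })
    return row


def leave_category_out(instruments: Sequence[HarmonizedInstrument],
                       scheme: CategoryScheme) -> pd.DataFrame:
    """IVW estimates excluding one biological category at a time.

    A SNP is excluded whenever the excluded label contains it (under any
    of its memberships).  Rows where fewer than 2 SNPs remain are flagged
    rather than computed.
    """
    if len(scheme.members) < 2:
        raise ValueError("leave_category_out needs >= 2 categories")
    rows = []
    for label in scheme.labels():
        snps = scheme.members[label]
        kept = [i for i in instruments if not _member(i, snps)]
        if len(kept) < 2:
            rows.append({"excluded_category": label, "n_snps": len(kept),
                         "computed": False})
            continue
        res = ivw(kept)
        rows.append(_result_row(res, excluded_category=label))
    return pd.DataFrame(rows)


def exclude_selected(instruments: Sequence[HarmonizedInstrument],
                     labels: Sequence[str],
                     scheme: CategoryScheme,
                     simex_config: Optional[SimexConfig] = None,
                     n_boot: int = 1000,
                     seed: Optional[int] = None) -> pd.DataFrame:
    """All three estimators after removing forward-selected categories.

    Runs IVW, MR-Egger (plain and SIMEX-corrected) and the weighted
    median on the dataset minus each selected label alone and minus all
    labels jointly.  With no labels, the single row block equals the
    all-SNP analyses.
    """
    variants: list[tuple[str, set[str]]] = [
        (lab, scheme.members.get(lab, set())) for lab in labels]
    if len(labels) > 1:
        joint: set[str] = set()
        for _, snps in variants:
            joint |= snps
        variants.append(("+".join(labels), joint))
    if not labels:
        variants = [("", set())]
    rows = []
    for tag, snps in variants:
        kept = [i for i in instruments if not _member(i, snps)]
        if len(kept) < 3:
            rows.append({"excluded_category": tag, "n_snps": len(kept),
                         "computed": False})
            continue
        for res in (ivw(kept), mr_egger(kept),
                    simex_egger(kept, simex_config),
                    weighted_median(kept, n_boot=n_boot, seed=seed)):
            rows.append(_result_row(res, excluded_category=tag))
    return pd.DataFrame(rows)
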