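"""Join external pCADD / VEP / SIFT annotations to called DNMs.

Annotations are consumed as a pre-computed table keyed by
(chrom, pos, ref, alt); computing the scores themselves is out of scope.
pCADD scores of 10 and 20 mark roughly the 10% and 1% most deleterious
possible substitutions, so coding or splice variants above a configurable
score (or SIFT-deleterious ones) are flagged as high-impact.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

KEY = ["chrom", "pos", "ref", "alt"]

#: standard VEP consequence severity order, most severe first (abridged to
#: the terms that occur in practice for SNVs)
VEP_SEVERITY = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intron_variant",
    "intergenic_variant",
)
_SEVERITY_RANK = {term: i for i, term in enumerate(VEP_SEVERITY)}

CODING_OR_SPLICE = frozenset(
    {
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "missense_variant",
        "splice_region_variant",
        "synonymous_variant",
    }
)


def most_severe(consequences: str | Sequence[str]) -> str:
    """Pick the most severe term from a VEP consequence string
    (``&``/``,``-separated) or sequence."""
    if isinstance(consequences, str):
        terms = [t for t in consequences.replace("&", ",").split(",") if t]
    else:
        terms = list(consequences)
    if not terms:
        return "intergenic_variant"
    return min(terms, key=lambda t: _SEVERITY_RANK.get(t, len(VEP_SEVERITY)))


def read_annotation_table(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in KEY + ["pcadd", "consequence"] if c not in tab.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    return tab


def join_annotations(dnms: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Left-join annotations onto DNMs; never drops a DNM.

    Unmatched DNMs carry NaN pcadd / "absent" sift; duplicate annotation
    keys with conflicting values raise a consistency error.
    """
    dup = annotations.duplicated(subset=KEY, keep=False)
    if dup.any():
        conflicting = annotations[dup].drop_duplicates()
        if conflicting.duplicated(subset=KEY, keep=False).any():
            bad = conflicting[conflicting.duplicated(subset=KEY, keep=False)]
            raise ValueError(
                "conflicting duplicate annotation keys:\n"
                + bad[KEY].drop_duplicates().to_string(index=False)
            )
        annotations = annotations.drop_duplicates(subset=KEY)
    out = dnms.merge(annotations, on=KEY, how="left", validate="many_to_one")
    if "sift" in out.columns:
        out["sift"] = out["sift"].fillna("absent")
    else:
        out["sift"] = "absent"
    if "consequence" in out.columns:
        out["consequence"] = out["consequence"].map(
            lambda c: most_severe(c) if isinstance(c, str) else c
        )
    n_unmatched = int(out["pcadd"].isna().sum()) if "pcadd" in out.columns else len(out)
    out.attrs["n_unmatched"] = n_unmatched
    return out


def summarize_by_consequence(
    annotated: pd.DataFrame, high_impact_pcadd: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-consequence counts and mean pCADD, plus the high-impact list.

    Means ignore absent scores. High impact = coding/splice consequence
    with pCADD above the threshold, or SIFT deleterious.
    """
    grouped = (
        annotated.groupby("consequence", dropna=False)
        .agg(count=("consequence", "size"), mean_pcadd=("pcadd", "mean"))
        .reset_index()
    )
    order = grouped["consequence"].map(
        lambda t: _SEVERITY_RANK.get(t, len(VEP_SEVERITY))
    )
    grouped = grouped.assign(_rank=order).sort_values("_rank").drop(columns="_rank")
    is_coding = annotated["consequence"].isin(CODING_OR_SPLICE)
    high = annotated[
        (is_coding & (annotated["pcadd"] > high_impact_pcadd))
        | (annotated["sift"] == "deleterious")
    ]
    return grouped.reset_index(drop=True), high.reset_index(drop=True)
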