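"""Mutational-spectrum classification.

Base changes are collapsed to the six pyrimidine-centred classes (the SBS96
convention): a purine reference (A/G) is reverse-complemented together with
its flanks, so every change reads as C>* or T>*. Transitions are C>T and
T>C; the Ti/Tv ratio is their count divided by the count of the four
transversion classes. A C>* change whose downstream base is G sits in a CpG
dinucleotide, where spontaneous deamination of methylated cytosine elevates
the C>T rate — the CpG fraction of C>T changes quantifies that signal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from pyfaidx import Fasta

PYRIMIDINES = ("C", "T")
PURINES = ("A", "G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six collapsed classes, transitions first
CLASSES = ("C>T", "T>C", "C>A", "C>G", "T>A", "T>G")
TRANSITIONS = frozenset({"C>T", "T>C"})

#: 96 trinucleotide context labels, e.g. "A[C>T]G"
CONTEXTS_96 = tuple(
    f"{up}[{cls}]{down}"
    for cls in sorted(CLASSES)
    for up in BASES
    for down in BASES
)


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


@dataclass(frozen=True)
class BaseChange:
    collapsed_class: str

    @property
    def is_transition(self) -> bool:
        return self.collapsed_class in TRANSITIONS


@dataclass(frozen=True)
class ContextualDNM:
    change: BaseChange
    upstream: str | None
    downstream: str | None

    @property
    def collapsed_class(self) -> str:
        return self.change.collapsed_class

    @property
    def context_label(self) -> str | None:
        if self.upstream is None or self.downstream is None:
            return None
        return f"{self.upstream}[{self.collapsed_class}]{self.downstream}"

    @property
    def is_cpg(self) -> bool:
        return self.collapsed_class.startswith("C") and self.downstream == "G"


def collapse_change(ref: str, alt: str) -> BaseChange:
    """Collapse an (ref, alt) substitution to its pyrimidine-centred class."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"bases must be one of ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in PURINES:
        ref, alt = complement(ref), complement(alt)
    return BaseChange(collapsed_class=f"{ref}>{alt}")


def context_of(window: str, pos: int, ref: str, alt: str) -> ContextualDNM:
    """Classify a substitution with its +/-1 bp context.

    ``window`` is the reference sequence containing the site; ``pos`` is the
    0-based index of the mutated base within ``window``. When the reference
    base is a purine, flanks are reverse-complemented and swapped along with
    the change. At a contig edge the context is marked unavailable
    (``upstream``/``downstream`` = None).
    """
    change = collapse_change(ref, alt)
    if not 0 <= pos < len(window):
        raise ValueError("pos outside window")
    if window[pos].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch: window has {window[pos]!r} at pos, "
            f"variant says {ref!r}"
        )
    up = window[pos - 1].upper() if pos >= 1 else None
    down = window[pos + 1].upper() if pos + 1 < len(window) else None
    if ref in PURINES:
        up, down = (
            complement(down) if down is not None else None,
            complement(up) if up is not None else None,
        )
    return ContextualDNM(change=change, upstream=up, downstream=down)


def contexts_from_fasta(
    fasta_path: str,
    sites: Iterable[tuple[str, int, str, str]],
) -> list[ContextualDNM]:
    """Classify (chrom, 1-based pos, ref, alt) sites against a reference
    FASTA."""
    fa = Fasta(str(fasta_path))
    out = []
    for chrom, pos, ref, alt in sites:
        seq = fa[chrom]
        lo = max(0, pos - 2)  # 0-based window start
        hi = min(len(seq), pos + 1)
        window = str(seq[lo:hi])
        out.append(context_of(window, pos - 1 - lo, ref, alt))
    return out


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts, proportions and headline ratios of a DNM set.

    Ratios with a zero denominator are ``None`` (undefined), never inf.
    """

    class_counts: Mapping[str, int]
    context_counts: Mapping[str, int]
    n_total: int

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {c: 0.0 for c in CLASSES}
        return {c: self.class_counts[c] / self.n_total for c in CLASSES}

    @property
    def titv_ratio(self) -> float | None:
        ti = sum(self.class_counts[c] for c in CLASSES if c in TRANSITIONS)
        tv = sum(self.class_counts[c] for c in CLASSES if c not in TRANSITIONS)
        return ti / tv if tv else None

    @property
    def ct_tc_ratio(self) -> float | None:
        tc = self.class_counts["T>C"]
        return self.class_counts["C>T"] / tc if tc else None

    @property
    def cpg_fraction_of_ct(self) -> float | None:
        ct = self.class_counts["C>T"]
        if not ct:
            return None
        cpg = sum(
            n
            for label, n in self.context_counts.items()
            if "[C>T]" in label and label.endswith("G")
        )
        return cpg / ct

    def context_matrix(self) -> pd.DataFrame:
        """16 contexts (rows: upstream x downstream) by 6 classes."""
        idx = [f"{u}_{d}" for u in BASES for d in BASES]
        mat = pd.DataFrame(0, index=idx, columns=list(CLASSES))
        for label, n in self.context_counts.items():
            up, rest = label.split("[", 1)
            cls, down = rest.split("]", 1)
            mat.loc[f"{up}_{down}", cls] += n
        return mat


def summarize_spectrum(dnms: Iterable[ContextualDNM]) -> SpectrumSummary:
    class_counts = Counter({c: 0 for c in CLASSES})
    context_counts: Counter[str] = Counter()
    n = 0
    for d in dnms:
        n += 1
        class_counts[d.collapsed_class] += 1
        label = d.context_label
        if label is not None:
            context_counts[label] += 1
    return SpectrumSummary(
        class_counts=dict(class_counts),
        context_counts=dict(context_counts),
        n_total=n,
    )


def spectrum_table(summary: SpectrumSummary) -> pd.DataFrame:
    props = summary.proportions
    return pd.DataFrame(
        {
            "class": list(CLASSES),
            "count": [summary.class_counts[c] for c in CLASSES],
            "proportion": [props[c] for c in CLASSES],
        }
    )
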