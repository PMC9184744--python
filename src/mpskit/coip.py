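"""dNSAF scoring and candidate filtering for co-IP spectral-count data.

Spectral counting quantifies protein abundance in a pulldown by the number of
peptide spectra matched to each protein. The distributed Normalized Spectral
Abundance Factor (dNSAF) corrects for peptides shared between proteins by
distributing each shared peptide's count among its sharers in proportion to
their unique counts, then length-normalizes and rescales so the per-sample
values sum to one:

    dSpC_k  = uSpC_k + sum over shared peptides p containing k of
              sSpC_p * uSpC_k / sum_{j in sharers(p)} uSpC_j
    dNSAF_k = (dSpC_k / L_k) / sum_i (dSpC_i / L_i)

If every sharer of a peptide has zero unique counts, that peptide's count is
split equally among the sharers. Candidate interactors are proteins whose
bait-pulldown dNSAF exceeds the IgG-control dNSAF (fold change strictly > 1;
proteins undetected in the control but present in the bait are kept with an
infinite fold change). Multi-bait designs are combined either by intersection
(proteins recovered with every bait) or by annotated pooling (union restricted
to, e.g., transmembrane proteins).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import AnalysisError

logger = logging.getLogger(__name__)

_TABLE_COLUMNS = {
    "protein_id",
    "length",
    "sample",
    "replicate",
    "peptide_id",
    "peptide_type",
    "count",
    "sharers",
}


@dataclass(frozen=True)
class CandidateList:
    """Ordered, duplicate-free protein list with filter provenance."""

    proteins: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise AnalysisError("CandidateList contains duplicates")

    def __iter__(self):
        return iter(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, pid) -> bool:
        return pid in self.proteins


def _validate_table(table: pd.DataFrame) -> None:
    missing = _TABLE_COLUMNS - set(table.columns)
    if missing:
        raise AnalysisError(f"spectral-count table is missing columns {sorted(missing)}")


def _dnsaf_one_replicate(sub: pd.DataFrame) -> pd.DataFrame:
    """dSpC and dNSAF for one (sample, replicate) slice of the long table."""
    unique = (
        sub[sub.peptide_type == "unique"].groupby("protein_id")["count"].sum()
    )
    lengths = sub.groupby("protein_id")["length"].first()
    uspc = unique.reindex(lengths.index, fill_value=0).astype(float)
    dspc = uspc.copy()

    shared = sub[sub.peptide_type == "shared"]
    # each shared peptide contributes once with its total count and sharer set
    for peptide_id, grp in shared.groupby("peptide_id"):
        sharers = sorted(
            set(itertools.chain.from_iterable(s.split(";") for s in grp["sharers"] if s))
        )
        if len(sharers) < 2:
            raise AnalysisError(f"shared peptide {peptide_id!r} names fewer than 2 proteins")
        counts = grp["count"].unique()
        if counts.size != 1:
            raise AnalysisError(
                f"shared peptide {peptide_id!r} has inconsistent totals across sharer rows"
            )
        total = float(counts[0])
        present = [s for s in sharers if s in uspc.index]
        denom = sum(uspc.get(s, 0.0) for s in present)
        for s in present:
            if denom > 0:
                dspc[s] += total * uspc[s] / denom
            else:
                dspc[s] += total / len(present)

    saf = dspc / lengths.astype(float)
    norm = saf.sum()
    if norm == 0:
        raise AnalysisError("all-zero sample: dNSAF normalizer is zero")
    out = pd.DataFrame(
        {"protein_id": lengths.index, "dSpC": dspc.values, "dNSAF": (saf / norm).values}
    )
    return out.reset_index(drop=True)


def compute_dnsaf(table: pd.DataFrame, sample: str, combine: str = "mean") -> pd.DataFrame:
    """Per-protein dNSAF for one sample of a long-format spectral-count table.

    Replicates are computed independently then combined (``combine="mean"``
    averages dNSAF across replicates; ``combine="none"`` returns the
    per-replicate table with a ``replicate`` column).
    """
    _validate_table(table)
    sub = table[table["sample"] == sample]
    if sub.empty:
        raise AnalysisError(f"sample {sample!r} not present in the table")
    per_rep = []
    for rep, grp in sub.groupby("replicate"):
        d = _dnsaf_one_replicate(grp)
        d["replicate"] = rep
        per_rep.append(d)
    all_reps = pd.concat(per_rep, ignore_index=True)
    if combine == "none":
        return all_reps
    if combine != "mean":
        raise AnalysisError(f"unknown replicate combination {combine!r}")
    out = (
        all_reps.groupby("protein_id")[["dSpC", "dNSAF"]]
        .mean()
        .reset_index()
    )
    return out


def fold_change_filter(
    bait: pd.DataFrame, control: pd.DataFrame, threshold: float = 1.0
) -> CandidateList:
    """Keep proteins whose bait dNSAF / control dNSAF is strictly above threshold.

    A protein undetected in the control (dNSAF 0) but present in the bait is
    kept with an infinite fold change; proteins absent from the bait table are
    dropped. Fold change 1 (equal abundance) is removed — "greater than", not
    "at least".
    """
    b = bait.set_index("protein_id")["dNSAF"]
    c = control.set_index("protein_id")["dNSAF"]
    kept = []
    fold_changes = {}
    for pid, v in b.items():
        if v <= 0:
            continue
        cv = float(c.get(pid, 0.0))
        fc = math_inf if cv == 0 else v / cv
        fold_changes[pid] = fc
        if fc > threshold:
            kept.append(pid)
    return CandidateList(
        tuple(kept),
        provenance={"filter": "dNSAF fold change", "threshold": threshold, "fold_changes": fold_changes},
    )


math_inf = float("inf")


def intersect_candidates(lists: list[CandidateList]) -> tuple[CandidateList, dict]:
    """Intersection across bait lists, plus exclusive Venn region counts.

    Returns the proteins present in *every* list (order of the first list) and
    a dict mapping each non-empty subset of list indices (a sorted tuple) to
    the number of proteins found in exactly those lists.
    """
    if len(lists) < 2:
        raise AnalysisError("intersect_candidates needs at least 2 lists")
    sets = [set(l.proteins) for l in lists]
    common = set.intersection(*sets)
    intersection = CandidateList(
        tuple(p for p in lists[0].proteins if p in common),
        provenance={"combination": "intersection", "n_lists": len(lists)},
    )
    venn: dict[tuple[int, ...], int] = {}
    universe = set.union(*sets)
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), r):
            inside = set.intersection(*(sets[i] for i in combo))
            outside = set.union(set(), *(sets[i] for i in range(len(sets)) if i not in combo))
            venn[combo] = len(inside - outside)
    assert sum(venn.values()) == len(universe)
    return intersection, venn


def pool_candidates(
    lists: list[CandidateList], annotation: dict[str, bool]
) -> CandidateList:
    """Union of candidate lists restricted to annotation-true proteins.

    Used for low-recovery classes (transmembrane proteins): pooling across
    baits trades specificity for inclusiveness. Proteins missing from the
    annotation are treated as False with a warning.
    """
    seen = []
    for lst in lists:
        for pid in lst:
            if pid in seen:
                continue
            if pid not in annotation:
                logger.warning("pool_candidates: %s missing from annotation; treated as False", pid)
                continue
            if annotation[pid]:
                seen.append(pid)
    return CandidateList(
        tuple(seen), provenance={"combination": "annotated pool", "n_lists": len(lists)}
    )
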