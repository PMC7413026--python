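"""TCR contig parsing, MAIT classification and clonotype construction.

MAIT cells are defined by the semi-invariant TCRa chain: TRAV1-2 joined
to TRAJ33, TRAJ12 or TRAJ20 on a productive TRA contig.  Cells are
eligible for repertoire analysis only when at least one productive
TRA and one productive TRB chain were assembled.

Two clonotype definitions are supported:

``exact_pair``
    cells sharing an identical (V, J, CDR3nt) alpha AND beta pair form a
    clone; cells with several productive chains are keyed by their
    lexicographically smallest alpha and beta (deterministic tie-break).

``shared_chain``
    cells are merged whenever they share at least one productive alpha
    nucleotide sequence and at least one productive beta nucleotide
    sequence (transitive closure), the convention used for droplet data
    where chain recovery is incomplete.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .datatypes import StructuralError

MAIT_TRAV = "TRAV1-2"
MAIT_TRAJ = frozenset({"TRAJ33", "TRAJ12", "TRAJ20"})

_ALLELE = re.compile(r"\*\d+$")


def strip_allele(gene: str) -> str:
    """Drop a trailing allele suffix ('TRAV1-2*01' -> 'TRAV1-2')."""
    return _ALLELE.sub("", gene.strip())


@dataclass(frozen=True)
class TcrChain:
    locus: str  # TRA or TRB
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str = ""
    productive: bool = True

    def __post_init__(self):
        if self.locus not in ("TRA", "TRB"):
            raise StructuralError(f"unknown locus '{self.locus}'")

    @property
    def key(self) -> tuple[str, str, str]:
        return (strip_allele(self.v_gene), strip_allele(self.j_gene), self.cdr3_nt)


@dataclass
class TcrRecord:
    cell_id: str
    chains: list[TcrChain] = field(default_factory=list)

    def productive(self, locus: str) -> list[TcrChain]:
        return [c for c in self.chains if c.locus == locus and c.productive]

    @property
    def eligible(self) -> bool:
        """True when >=1 productive TRA and >=1 productive TRB were assembled."""
        return bool(self.productive("TRA")) and bool(self.productive("TRB"))


@dataclass
class Clonotype:
    clonotype_id: str
    defining_alpha: tuple[str, str, str]
    defining_beta: tuple[str, str, str]
    member_cell_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_cell_ids)

    @property
    def clonal(self) -> bool:
        return self.size >= 2


def records_from_contigs(contigs: pd.DataFrame) -> list[TcrRecord]:
    """Group a contig table (one chain per row) into per-cell records."""
    records: dict[str, TcrRecord] = {}
    for row in contigs.itertuples(index=False):
        rec = records.setdefault(str(row.cell_id), TcrRecord(cell_id=str(row.cell_id)))
        rec.chains.append(
            TcrChain(
                locus=str(row.locus),
                v_gene=str(row.v_gene),
                j_gene=str(row.j_gene),
                cdr3_nt=str(row.cdr3_nt),
                cdr3_aa=str(getattr(row, "cdr3_aa", "")),
                productive=bool(row.productive),
            )
        )
    return list(records.values())


def is_mait_chain(chain: TcrChain) -> bool:
    return (
        chain.locus == "TRA"
        and chain.productive
        and strip_allele(chain.v_gene) == MAIT_TRAV
        and strip_allele(chain.j_gene) in MAIT_TRAJ
    )


def classify_mait(records: Iterable[TcrRecord]) -> pd.DataFrame:
    """Per-cell MAIT flag from the semi-invariant alpha chain.

    Returns a frame (cell_id, eligible, is_mait).  Cells lacking a
    productive TRA+TRB pair are flagged ineligible and never MAIT.
    A cell with several productive alpha chains is MAIT if ANY of them
    matches TRAV1-2 with TRAJ33/12/20.
    """
    rows = []
    for rec in records:
        eligible = rec.eligible
        is_mait = eligible and any(is_mait_chain(c) for c in rec.productive("TRA"))
        rows.append((rec.cell_id, eligible, is_mait))
    return pd.DataFrame(rows, columns=["cell_id", "eligible", "is_mait"])


def apply_mait_labels(annotations: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Overwrite the subset of TCR-defined MAIT cells; others keep their label."""
    ann = annotations.copy()
    mait_ids = set(flags.loc[flags["is_mait"], "cell_id"])
    ann.loc[ann["cell_id"].isin(mait_ids), "subset"] = "MAIT"
    return ann


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_clonotypes(
    records: Sequence[TcrRecord],
    mode: Literal["exact_pair", "shared_chain"] = "exact_pair",
) -> list[Clonotype]:
    """Partition eligible cells into clonotypes under the chosen definition."""
    eligible = [r for r in records if r.eligible]
    if mode == "exact_pair":
        groups: dict[tuple, list[str]] = {}
        for rec in eligible:
            alpha = min(c.key for c in rec.productive("TRA"))
            beta = min(c.key for c in rec.productive("TRB"))
            groups.setdefault((alpha, beta), []).append(rec.cell_id)
        items = sorted(groups.items())
    elif mode == "shared_chain":
        # Cells sharing any productive alpha nt sequence AND any productive
        # beta nt sequence are merged; transitive closure via union-find.
        uf = _UnionFind()
        by_alpha: dict[str, list[str]] = {}
        chains_a: dict[str, set[str]] = {}
        chains_b: dict[str, set[str]] = {}
        for rec in eligible:
            chains_a[rec.cell_id] = {c.cdr3_nt for c in rec.productive("TRA")}
            chains_b[rec.cell_id] = {c.cdr3_nt for c in rec.productive("TRB")}
            for nt in chains_a[rec.cell_id]:
                by_alpha.setdefault(nt, []).append(rec.cell_id)
        for rec in eligible:
            uf.find(rec.cell_id)
            # candidate partners share >=1 alpha; require >=1 shared beta too
            for nt in chains_a[rec.cell_id]:
                for other in by_alpha[nt]:
                    if other != rec.cell_id and chains_b[rec.cell_id] & chains_b[other]:
                        uf.union(rec.cell_id, other)
        groups2: dict[str, list[str]] = {}
        for rec in eligible:
            groups2.setdefault(uf.find(rec.cell_id), []).append(rec.cell_id)
        by_cell = {r.cell_id: r for r in eligible}
        items = []
        for members in groups2.values():
            rep = by_cell[min(members)]
            alpha = min(c.key for c in rep.productive("TRA"))
            beta = min(c.key for c in rep.productive("TRB"))
            items.append(((alpha, beta), sorted(members)))
        items.sort()
    else:
        raise ValueError(f"unknown clonotype mode '{mode}'")

    return [
        Clonotype(
            clonotype_id=f"clone{idx:05d}",
            defining_alpha=alpha,
            defining_beta=beta,
            member_cell_ids=sorted(members),
        )
        for idx, ((alpha, beta), members) in enumerate(items, start=1)
    ]


def clonotype_table(clonotypes: Sequence[Clonotype]) -> pd.DataFrame:
    """Flat per-clonotype summary table."""
    rows = []
    for c in clonotypes:
        rows.append(
            {
                "clonotype_id": c.clonotype_id,
                "alpha_v": c.defining_alpha[0],
                "alpha_j": c.defining_alpha[1],
                "alpha_cdr3_nt": c.defining_alpha[2],
                "beta_v": c.defining_beta[0],
                "beta_j": c.defining_beta[1],
                "beta_cdr3_nt": c.defining_beta[2],
                "size": c.size,
                "clonal": c.clonal,
            }
        )
    return pd.DataFrame(rows)


def dominant_clonotype_frequency(clonotypes: Sequence[Clonotype]) -> float:
    """Fraction of cells belonging to the largest clonotype."""
    if not clonotypes:
        raise ValueError("empty clonotype list")
    total = sum(c.size for c in clonotypes)
    return max(c.size for c in clonotypes) / total


def cell_to_clonotype(clonotypes: Sequence[Clonotype]) -> pd.Series:
    """Map cell_id -> clonotype_id."""
    mapping = {}
    for c in clonotypes:
        for cid in c.member_cell_ids:
            mapping[cid] = c.clonotype_id
    return pd.Series(mapping, name="clonotype_id")


def vj_usage(
    records: Sequence[TcrRecord],
    annotations: pd.DataFrame,
    group_by: Sequence[str] = ("tissue",),
    subset: str = "MAIT",
) -> pd.DataFrame:
    """Relative TRAJ (alpha) and TRBV (beta) segment usage among MAIT cells.

    Counts one alpha J segment and one beta V segment per cell (the
    lexicographically smallest productive chain, consistent with the
    exact-pair clonotype keying) so that expanded clones contribute their
    full cell count to their segment bins.  Frequencies sum to 1 within
    each (stratum, segment-class).  Strata with no cells of the requested
    subset are omitted with a warning.
    """
    ann = annotations.set_index("cell_id")
    flags = classify_mait(records).set_index("cell_id")
    rows = []
    for rec in records:
        if not rec.eligible or rec.cell_id not in ann.index:
            continue
        label = "MAIT" if flags.loc[rec.cell_id, "is_mait"] else ann.loc[rec.cell_id, "subset"]
        if label != subset:
            continue
        stratum = tuple(ann.loc[rec.cell_id, col] for col in group_by)
        alpha = min(c.key for c in rec.productive("TRA"))
        beta = min(c.key for c in rec.productive("TRB"))
        rows.append((*stratum, "TRAJ", alpha[1]))
        rows.append((*stratum, "TRBV", beta[0]))
    if not rows:
        import warnings

        warnings.warn(f"no eligible cells of subset '{subset}' in any stratum")
        return pd.DataFrame(columns=[*group_by, "segment_class", "segment", "count", "frequency"])
    df = pd.DataFrame(rows, columns=[*group_by, "segment_class", "segment"])
    counts = (
        df.groupby([*group_by, "segment_class", "segment"]).size().rename("count").reset_index()
    )
    totals = counts.groupby([*group_by, "segment_class"])["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts
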