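"""Group and subgroup assignment for WRKY proteins.

Structural rules drive the main groups: two WRKY domains (or one domain
carrying two tandem zinc fingers) place a protein in group I; a single domain
with a C2HC finger places it in group III; a single domain with a C2H2 (or
variant) finger places it in group II.  The five subgroups of group II are
not structurally defined — they are assigned by placing the query domain
against a labelled reference panel, either by nearest p-distance or by
joining a neighbor-joining tree and reading the smallest mixed clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domain_scan import WRKYDomain
from .evolution import align_pair
from .phylo import neighbor_joining, p_distance, progressive_msa

SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe")


@dataclass
class GroupAssignment:
    protein_id: str
    group: str
    evidence: str  # structural_rule | reference_placement
    domain_labels: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def assign_group(domains: list[WRKYDomain]) -> GroupAssignment:
    """Assign the main group (I / II-pending / III) from the domain inventory.

    Raises ValueError on an empty domain list: a protein without any WRKY
    domain is not a family member.
    """
    if not domains:
        raise ValueError("no WRKY domains: protein is not a family member")
    pid = domains[0].protein_id
    if len(domains) >= 2:
        labels = [f"{pid}-N", f"{pid}-C"][: len(domains)]
        return GroupAssignment(pid, "I", "structural_rule", domain_labels=labels)
    dom = domains[0]
    if dom.n_fingers >= 2:
        # one heptapeptide but two tandem fingers: a degenerate two-domain gene
        return GroupAssignment(
            pid, "I", "structural_rule", domain_labels=[pid], flags=["extra_fingers"]
        )
    if dom.finger_type == "C2HC":
        return GroupAssignment(pid, "III", "structural_rule", domain_labels=[pid])
    if dom.finger_type in ("C2H2", "variant-C2H2"):
        return GroupAssignment(pid, "II", "structural_rule", domain_labels=[pid])
    # incomplete finger: kept in the family, subgroup decided by references
    return GroupAssignment(
        pid, "II", "structural_rule", domain_labels=[pid], flags=["incomplete_finger"]
    )


def _pairwise_p_distance(a: str, b: str) -> float:
    aln = align_pair(a, b, mode="global-affine")
    ra, rb = aln.aligned_a, aln.aligned_b
    compared = mismatches = 0
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            continue
        compared += 1
        mismatches += x != y
    if compared == 0:
        return 1.0
    return mismatches / compared


def _nearest(query: str, references: list[tuple[str, str]]) -> tuple[str, bool]:
    """Label of the reference with the smallest p-distance; flags exact ties.

    Ties are broken by first-in-file order of the reference panel.
    """
    best_label, best_d, tied = None, None, False
    for label, seq in references:
        d = _pairwise_p_distance(query, seq)
        if best_d is None or d < best_d - 1e-12:
            best_label, best_d, tied = label, d, False
        elif abs(d - best_d) <= 1e-12 and label != best_label:
            tied = True
    return best_label, tied


def assign_subgroup(
    query_domain: str,
    reference_domains: list[tuple[str, str]],
    method: str = "tree",
) -> tuple[str, bool]:
    """Place one query domain sequence against a labelled reference panel.

    ``reference_domains`` is a list of (subgroup_label, sequence).  Returns
    (label, tie_flag).  Method "nearest" picks the reference at the smallest
    p-distance; "tree" builds an NJ tree of query + references and assigns the
    majority label of the smallest clade containing the query and at least one
    reference, falling back to "nearest" on ties.
    """
    if not reference_domains:
        raise ValueError("empty reference panel")
    if method == "nearest":
        return _nearest(query_domain, reference_domains)
    if method != "tree":
        raise ValueError(f"unknown method {method!r}")
    if len(reference_domains) == 1:
        return reference_domains[0][0], False

    names = ["__query__"] + [f"ref{i}" for i in range(len(reference_domains))]
    label_of = {f"ref{i}": lab for i, (lab, _) in enumerate(reference_domains)}
    seqs = [query_domain] + [seq for _, seq in reference_domains]
    aln = progressive_msa(seqs)
    dm = p_distance(aln, labels=names)
    tree = neighbor_joining(dm)

    leaf = next(nd for nd in tree.leaf_node_iter() if nd.taxon.label == "__query__")
    node = leaf.parent_node
    while node is not None:
        labels = [
            label_of[t.label]
            for t in (nd.taxon for nd in node.leaf_iter())
            if t.label in label_of
        ]
        if labels:
            counts: dict[str, int] = {}
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
            top = max(counts.values())
            winners = [lab for lab, c in counts.items() if c == top]
            if len(winners) == 1:
                return winners[0], False
            return _nearest(query_domain, reference_domains)
        node = node.parent_node
    return _nearest(query_domain, reference_domains)  # pragma: no cover
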