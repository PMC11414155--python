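"""Mating-type assignment from a partial HD2 amplicon alignment.

Main types are assigned by nearest reference sequence under p-distance with
a similarity threshold; queries beyond the threshold for every reference
are single-linkage clustered among themselves and become novel types.
Within a main type, alleles are distinguished by the translated amino-acid
sequence: only substitutions that alter the protein split an allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from ._codon_tables import AA, STOP_CODONS
from .io import Alignment
from .distances import p_distance

logger = logging.getLogger(__name__)


@dataclass
class MatTypeAssignment:
    isolate_id: str
    main_type: str
    allele: str
    aa_sequence: str

    def to_dict(self) -> dict:
        return {
            "isolate_id": self.isolate_id,
            "main_type": self.main_type,
            "allele": self.allele,
            "aa_sequence": self.aa_sequence,
        }


def translate_partial(aln: Alignment) -> dict[str, str]:
    """Standard-code translation of every record from the frame offset.

    Codons containing '-' or 'N' become 'X'; a trailing incomplete codon is
    dropped; internal stop codons translate to '*' with a warning (record
    retained).
    """
    if aln.frame is None:
        raise ValueError("alignment has no frame annotation")
    out: dict[str, str] = {}
    for rid, seq in zip(aln.ids, aln.seqs):
        coding = seq[aln.frame :]
        aas = []
        for k in range(len(coding) // 3):
            cod = coding[3 * k : 3 * k + 3]
            if cod in AA:
                if cod in STOP_CODONS and k < len(coding) // 3 - 1:
                    logger.warning(
                        "internal stop codon in %r at codon %d", rid, k + 1
                    )
                aas.append(AA[cod])
            else:
                aas.append("X")
        out[rid] = "".join(aas)
    return out


def _single_linkage_clusters(
    ids: list[str], seqs: dict[str, str], max_dist: float
) -> list[list[str]]:
    """Single-linkage clusters at threshold max_dist (union-find)."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i_pos, a in enumerate(ids):
        for b in ids[i_pos + 1 :]:
            if p_distance(seqs[a], seqs[b]) <= max_dist:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    return [sorted(c) for c in clusters.values()]


def assign_main_types(
    aln: Alignment,
    references: Optional[Alignment],
    max_dist: float = 0.03,
) -> dict[str, str]:
    """Assign each query its nearest reference's type if within ``max_dist``
    p-distance; cluster the remainder into novel types.

    Reference record ids are the type labels (e.g. "MAT1".."MAT7"); several
    references may share a type via ids like "MAT3|a" (label before '|').
    Ties between equidistant references break toward the lexicographically
    smaller type label (logged). Novel clusters are labelled "novel-1",
    "novel-2", ... ordered by decreasing size then smallest member id.
    With ``references=None`` every query goes through novel clustering (de
    novo typing). Identical query sequences are deduplicated before typing.
    """
    if references is not None:
        if references.n == 0:
            raise ValueError("empty reference set")
        if aln.length != references.length:
            raise ValueError(
                "query and reference alignments differ in length; align "
                "them together first"
            )
        ref_types = [rid.split("|")[0] for rid in references.ids]
    else:
        ref_types = []

    # deduplicate identical query sequences
    seq_to_ids: dict[str, list[str]] = {}
    for rid, s in zip(aln.ids, aln.seqs):
        seq_to_ids.setdefault(s, []).append(rid)
    uniq_seqs = sorted(seq_to_ids)  # sort for input-order invariance

    assigned: dict[str, str] = {}
    unassigned: list[str] = []
    for s in uniq_seqs:
        dists = (
            [p_distance(s, r) for r in references.seqs]
            if references is not None
            else []
        )
        dmin = min(dists) if dists else float("inf")
        if dmin <= max_dist:
            cands = sorted(
                {ref_types[k] for k, dv in enumerate(dists) if dv == dmin}
            )
            if len(cands) > 1:
                logger.info(
                    "tie between reference types %s for %s; taking %s",
                    cands, seq_to_ids[s], cands[0],
                )
            assigned[s] = cands[0]
        else:
            unassigned.append(s)

    if unassigned:
        rep_ids = {s: seq_to_ids[s][0] for s in unassigned}
        clusters = _single_linkage_clusters(
            [rep_ids[s] for s in unassigned],
            {rep_ids[s]: s for s in unassigned},
            max_dist,
        )
        clusters.sort(key=lambda c: (-len(c), min(c)))
        id_to_seq = {rep_ids[s]: s for s in unassigned}
        for k, cluster in enumerate(clusters, start=1):
            for rep in cluster:
                assigned[id_to_seq[rep]] = f"novel-{k}"

    out: dict[str, str] = {}
    for s, ids in seq_to_ids.items():
        for rid in ids:
            out[rid] = assigned[s]
    return out


def assign_alleles(
    main_types: dict[str, str], aa_sequences: dict[str, str]
) -> list[MatTypeAssignment]:
    """Split each main type into alleles by exact amino-acid identity.

    Allele groups are numbered by decreasing size, then by the
    lexicographically smallest amino-acid sequence; a type with a single
    amino-acid variant keeps its bare label.
    """
    if set(main_types) != set(aa_sequences):
        diff = sorted(set(main_types) ^ set(aa_sequences))
        raise ValueError(f"isolate sets differ: {diff}")
    by_type: dict[str, dict[str, list[str]]] = {}
    for rid in sorted(main_types):
        t = main_types[rid]
        by_type.setdefault(t, {}).setdefault(aa_sequences[rid], []).append(rid)
    out: list[MatTypeAssignment] = []
    for t in sorted(by_type):
        groups = sorted(
            by_type[t].items(), key=lambda kv: (-len(kv[1]), kv[0])
        )
        single = len(groups) == 1
        for k, (aa, ids) in enumerate(groups, start=1):
            label = t if single else f"{t}.{k}"
            for rid in ids:
                out.append(
                    MatTypeAssignment(
                        isolate_id=rid, main_type=t, allele=label, aa_sequence=aa
                    )
                )
    out.sort(key=lambda a: a.isolate_id)
    return out


def count_alleles(assignments: list[MatTypeAssignment]) -> tuple[int, int]:
    """(number of main types, number of distinct alleles)."""
    if not assignments:
        raise ValueError("no assignments")
    types = {a.main_type for a in assignments}
    alleles = {(a.main_type, a.allele) for a in assignments}
    return len(types), len(alleles)


def write_assignments(assignments: list[MatTypeAssignment], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("isolate_id\tmain_type\tallele\taa_sequence\n")
        for a in assignments:
            fh.write(f"{a.isolate_id}\t{a.main_type}\t{a.allele}\t{a.aa_sequence}\n")
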