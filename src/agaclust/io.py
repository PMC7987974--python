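"""File interfaces: FASTA proteins/CDS, substitution tables, fit reports."""

from __future__ import annotations

import json
from typing import Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .stats import ClusterStat, DistanceProfile
from .types import ProteinRecord, Substitution

SUBSTITUTION_COLUMNS = [
    "protein_id",
    "position",
    "from_aa",
    "to_aa",
    "parent_codon",
    "mismatch_class",
    "ef",
]


def read_proteins(
    fasta_path, cds_path: Optional[str] = None
) -> dict[str, ProteinRecord]:
    """Protein records from FASTA, optionally paired with a CDS FASTA by id.

    CDS entries may carry a trailing stop codon; it is stripped before the
    translation consistency check.
    """
    cds_map: dict[str, str] = {}
    if cds_path is not None:
        for rec in SeqIO.parse(str(cds_path), "fasta"):
            cds = str(rec.seq).upper().replace("T", "U")
            if len(cds) % 3 == 0 and cds[-3:] in ("UAA", "UAG", "UGA"):
                cds = cds[:-3]
            cds_map[rec.id] = cds
    out = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out[rec.id] = ProteinRecord(
            id=rec.id, sequence=str(rec.seq).upper(), cds=cds_map.get(rec.id)
        )
    return out


def write_proteins(proteins, path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_substitution_table(path) -> tuple[list[Substitution], dict[Substitution, float]]:
    """Substitutions and their E_f values from TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SUBSTITUTION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"substitution table missing columns: {missing}")
    subs, efs = [], {}
    for _, row in df.iterrows():
        sub = Substitution(
            protein_id=str(row["protein_id"]),
            position=int(row["position"]),
            from_aa=str(row["from_aa"]),
            to_aa=str(row["to_aa"]),
            parent_codon=None
            if pd.isna(row.get("parent_codon"))
            else str(row["parent_codon"]),
            mismatch_class=None
            if pd.isna(row.get("mismatch_class"))
            else str(row["mismatch_class"]),
        )
        subs.append(sub)
        if "ef" in df.columns and not pd.isna(row["ef"]):
            efs[sub] = float(row["ef"])
    return subs, efs


def write_substitution_table(efs: Mapping[Substitution, float], path) -> None:
    rows = [
        {
            "protein_id": s.protein_id,
            "position": s.position,
            "from_aa": s.from_aa,
            "to_aa": s.to_aa,
            "parent_codon": s.parent_codon or "",
            "mismatch_class": s.mismatch_class or "",
            "ef": ef,
        }
        for s, ef in efs.items()
    ]
    pd.DataFrame(rows, columns=SUBSTITUTION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cluster_stats(stats: list[ClusterStat], path) -> None:
    rows = []
    for st in stats:
        row = {
            "cluster": st.pattern_label,
            "ef_first": st.ef_first,
            "ef_second": st.ef_second,
            "ef_cluster": st.ef_cluster,
            "amplification": st.amplification,
            "efnext": st.efnext,
            "estimator": st.estimator_used,
            "d_list": ",".join(map(str, st.d_list)),
            "upper_limit": st.upper_limit,
        }
        row.update({f"condition_{k}": v for k, v in st.condition.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fit_report(profiles: Mapping[str, DistanceProfile], path) -> None:
    report = {}
    for aga, profile in profiles.items():
        entry = {
            "reference": profile.reference,
            "anchor": profile.anchor,
            "points": profile.points.to_dict(orient="records"),
        }
        if profile.fit is not None:
            entry["fit"] = {
                "q": profile.fit.q,
                "q_ci": list(profile.fit.q_ci),
                "c": profile.fit.c,
                "n_boot": profile.fit.n_boot,
                "degenerate": profile.fit.degenerate,
            }
        report[aga] = entry
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
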