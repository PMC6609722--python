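"""Plain-text readers and writers for cohorts, networks and genotypes.

Abundance and clinical tables travel as TSV (subjects in rows), ground truth
as JSON, genotypes as dosage TSV or minimal single-ALT VCF (GT field only).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .genetics import GenotypeMatrix
from .panel import MetabolitePanel
from .synthetic import TIME_POINTS, CohortDataset, GroundTruth

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_network_json",
    "write_edge_list",
]


def write_cohort(dataset: CohortDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tp in TIME_POINTS:
        dataset.abundances[tp].to_csv(out / f"abundance_{tp}.tsv", sep="\t", index_label="subject_id")
    dataset.clinical.to_csv(out / "clinical.tsv", sep="\t", index_label="subject_id")
    dataset.panel.to_tsv(out / "panel.tsv")


def read_cohort(in_dir) -> CohortDataset:
    src = Path(in_dir)
    abundances = {}
    for tp in TIME_POINTS:
        df = pd.read_csv(src / f"abundance_{tp}.tsv", sep="\t", index_col="subject_id")
        df.index.name = None
        abundances[tp] = df
    clinical = pd.read_csv(src / "clinical.tsv", sep="\t", index_col="subject_id")
    clinical.index.name = None
    panel_path = src / "panel.tsv"
    if panel_path.exists():
        panel = MetabolitePanel.from_tsv(panel_path)
    else:
        from .panel import generic_panel

        panel = generic_panel(abundances["t0"].shape[1])
    return CohortDataset(abundances=abundances, clinical=clinical, panel=panel)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "precision_matrix": truth.precision_matrix.tolist(),
        "community_labels": truth.community_labels.tolist(),
        "exposure_effects": {k: np.asarray(v).tolist() for k, v in truth.exposure_effects.items()},
        "differential_edges": [list(e) for e in truth.differential_edges],
        "genetic_effects": [list(e) for e in truth.genetic_effects],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        precision_matrix=np.asarray(payload["precision_matrix"], dtype=float),
        community_labels=np.asarray(payload["community_labels"], dtype=int),
        exposure_effects={k: np.asarray(v, dtype=float) for k, v in payload["exposure_effects"].items()},
        differential_edges=[tuple(e) for e in payload["differential_edges"]],
        genetic_effects=[tuple(e) for e in payload["genetic_effects"]],
    )


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    G.dosages.to_csv(path, sep="\t", index_label="subject_id", na_rep="NA")


def read_dosage_tsv(path, variant_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    dosages = pd.read_csv(path, sep="\t", index_col="subject_id", na_values=["NA"])
    dosages.index.name = None
    if variant_meta is None:
        variant_meta = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, dosages.shape[1] + 1),
                "ref": "A",
                "alt": "G",
            },
            index=pd.Index(dosages.columns, name="variant_id"),
        )
    return GenotypeMatrix(dosages=dosages, variant_meta=variant_meta)


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with a single ALT allele and GT-only genotypes."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(s) for s in G.dosages.index),
    ]
    arr = G.dosages.to_numpy(dtype=float)
    for j, vid in enumerate(G.dosages.columns):
        meta = G.variant_meta.loc[vid]
        gts = ["./." if np.isnan(d) else _GT_CODE[d] for d in arr[:, j]]
        lines.append(
            f"{meta['chrom']}\t{int(meta['pos'])}\t{vid}\t{meta['ref']}\t{meta['alt']}"
            f"\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a dosage matrix (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(f"variant {rec.ID} is not biallelic")
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        gt = rec.gt_types.astype(float)
        dose = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dose)
    dosages = pd.DataFrame(np.array(rows).T, index=subjects, columns=ids)
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="variant_id"),
    )
    return GenotypeMatrix(dosages=dosages, variant_meta=meta)


def write_edge_list(summary_or_network, path) -> None:
    """Edge list TSV: node_a, node_b, weight (+ inclusion_frequency if known)."""
    from .network import BootstrapSummary, PartialCorrelationNetwork

    if isinstance(summary_or_network, PartialCorrelationNetwork):
        df = summary_or_network.edge_list()
    elif isinstance(summary_or_network, BootstrapSummary):
        w = summary_or_network.median_weights
        freq = summary_or_network.inclusion_frequency
        labels = summary_or_network.node_labels
        i, j = np.nonzero(np.triu((w != 0) | (freq > 0), 1))
        df = pd.DataFrame(
            {
                "node_a": [labels[a] for a in i],
                "node_b": [labels[b] for b in j],
                "weight": w[i, j],
                "inclusion_frequency": freq[i, j],
            }
        )
    else:
        raise ValidationError("expected a PartialCorrelationNetwork or BootstrapSummary")
    df.to_csv(path, sep="\t", index=False)


def write_network_json(network, path) -> None:
    from .network import PartialCorrelationNetwork

    if not isinstance(network, PartialCorrelationNetwork):
        raise ValidationError("expected a PartialCorrelationNetwork")
    payload = {
        "node_labels": network.node_labels,
        "weights": network.weights.tolist(),
        "penalty": network.penalty,
        "ebic": network.ebic,
        "sample_size": network.sample_size,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
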