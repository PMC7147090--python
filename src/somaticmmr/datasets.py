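"""Bundled reference objects: the published per-tumor table, a synthetic
30-signature reference, and a synthetic 578-gene panel.

``table1_fixture`` transcribes the published case-by-case molecular table of
30 breast carcinomas (11 dMMR Lynch-syndrome, 9 pMMR Lynch-syndrome, 10
non-carrier) and is the golden input for the group-level report. The signature
matrix and gene panel are deterministic synthetic stand-ins with the right
shape and composition (30 signatures x 96 channels; 578 genes over 4 Mb with
47 epigenetic-regulation and 45 DNA-repair genes), suitable for simulation and
testing; they do not reproduce any third-party database content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    GeneCategory,
    GenePanel,
    GermlineKind,
    Group,
    IhcResult,
    MmrGene,
    MsiResult,
    SignatureMatrix,
    TumorSample,
)

# sample_id, group, gene, germline kind, IHC, MSI, second-hit code, mutations/Mb
_TABLE1_ROWS = [
    ("BC5_31814T", Group.dMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "negat", "MSS", "L", 141),
    ("BC6_31489T", Group.dMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "negat", "MSI", "L, s", 725),
    ("BC11_31501T", Group.dMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "negat", "MSI", "L", 24),
    ("BC11_31533T", Group.dMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "negat", "MSS", "L", 5),
    ("BC12_31491T", Group.dMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "negat", "MSI", "None", 22),
    ("BC14_33229T", Group.dMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "negat", "MSS", "s", 662),
    ("BC9_33225T", Group.dMMR_LS_BC, MmrGene.MLH1, GermlineKind.point, "negat", "MSI", "L", 29),
    ("BC7_33223T", Group.dMMR_LS_BC, MmrGene.MSH2, GermlineKind.point, "negat", "MSI", "L", 15),
    ("BC37_33228T", Group.dMMR_LS_BC, MmrGene.MSH2, GermlineKind.large_deletion, "negat", "MSI", "s", 12),
    ("BC1_33203T", Group.dMMR_LS_BC, MmrGene.MSH6, GermlineKind.large_deletion, "negat", "MSS", "s", 35),
    ("BC1_31528T", Group.dMMR_LS_BC, MmrGene.MSH6, GermlineKind.large_deletion, "negat", "MSS", "s", 246),
    ("BC5_31495T", Group.pMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "posit", "MSS", "None", 31),
    ("BC13_31486T", Group.pMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "posit", "MSS", "s", 85),
    ("BC4_31514T", Group.pMMR_LS_BC, MmrGene.MLH1, GermlineKind.large_deletion, "posit", "MSS", "L", 4),
    ("BC38_31510T", Group.pMMR_LS_BC, MmrGene.MLH1, GermlineKind.point, "posit", "MSS", "s", 53),
    ("BC8_33226T", Group.pMMR_LS_BC, MmrGene.MSH2, GermlineKind.large_deletion, "posit", "MSS", "None", 8),
    ("BC10_33221T", Group.pMMR_LS_BC, MmrGene.MSH2, GermlineKind.point, "posit", "MSS", "L", 2),
    ("BC2_31518T", Group.pMMR_LS_BC, MmrGene.MSH6, GermlineKind.large_deletion, "posit", "MSS", "s", 108),
    ("BC39_33217T", Group.pMMR_LS_BC, MmrGene.MSH6, GermlineKind.large_deletion, "posit", "MSS", "ND", 2),
    ("BC40_31503T", Group.pMMR_LS_BC, MmrGene.MSH6, GermlineKind.point, "posit", "MSS", "None", 5),
    ("BC24_31711T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A", 1),
    ("BC23_33198T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A", 1),
    ("BC21_31702T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A", 5),
    ("BC20_33207T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A (ds)", 306),
    ("BC19_31706T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A", 2),
    ("BC18_33215T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A", 3),
    ("BC16_33205T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A (ds)", 393),
    ("BC43_33196T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A", 5),
    ("BC15_31696T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A (ds)", 161),
    ("BC17_31692T", Group.NC_BC, MmrGene.none, GermlineKind.none, "posit", "MSS", "N/A", 2),
]

MMR_PROTEINS = ("MLH1", "MSH2", "MSH6", "PMS2")


@dataclass(frozen=True)
class Table1Fixture:
    """Deterministic transcription of the 30 published breast carcinomas."""

    samples: tuple[TumorSample, ...]
    mutations_per_mb: dict[str, float]
    second_hit_code: dict[str, str]


def table1_fixture() -> Table1Fixture:
    samples = []
    per_mb: dict[str, float] = {}
    codes: dict[str, str] = {}
    for sid, group, gene, kind, ihc_str, msi_str, code, rate in _TABLE1_ROWS:
        if ihc_str == "negat":
            # the predisposing protein is the one lost
            ihc = {p: (IhcResult.absent if p == gene.value else IhcResult.present) for p in MMR_PROTEINS}
        else:
            ihc = {p: IhcResult.present for p in MMR_PROTEINS}
        msi_state = MsiResult.unstable if msi_str == "MSI" else MsiResult.stable
        samples.append(
            TumorSample(
                sample_id=sid,
                group=group,
                predisposing_gene=gene,
                germline_variant_kind=kind,
                ihc=ihc,
                msi_markers={"BAT25": msi_state, "BAT26": msi_state},
            )
        )
        per_mb[sid] = float(rate)
        codes[sid] = code
    return Table1Fixture(
        samples=tuple(samples), mutations_per_mb=per_mb, second_hit_code=codes
    )


def synthetic_reference_signatures(n_signatures: int = 30, concentration: float = 0.3) -> SignatureMatrix:
    """Synthetic reference of ``n_signatures`` distinct 96-channel signatures.

    Profiles are Dirichlet draws from a fixed generator, so the matrix is
    deterministic, reasonably sparse, and the signatures are close to mutually
    distinguishable. This is a synthetic stand-in with the structure of the
    canonical 30-signature reference, not its content.
    """
    rng = np.random.default_rng(961230)
    probs = rng.dirichlet(np.full(96, concentration), size=n_signatures)
    probs /= probs.sum(axis=1, keepdims=True)
    ids = tuple(str(i + 1) for i in range(n_signatures))
    return SignatureMatrix(signature_ids=ids, probs=probs)


_NAMED_PANEL_GENES = (
    "MLH1", "MSH2", "MSH6", "PMS2", "TP53", "PIK3CA", "PTEN", "ERBB2",
    "KMT2C", "KMT2D", "ARID1A", "CREBBP", "EP300", "SETD2", "BRCA1",
    "BRCA2", "ATM", "POLE", "POLD1", "GATA3", "RB1", "MAP3K1", "MYC", "CCND1",
)


def synthetic_panel(n_genes: int = 578, footprint_mb: float = 4.0) -> GenePanel:
    """Synthetic comprehensive cancer panel: ``n_genes`` genes over ``footprint_mb`` Mb.

    The first genes carry familiar symbols (the four MMR genes among them);
    the remainder are synthetic placeholders. 47 genes are tagged as
    epigenetic regulators and 45 as DNA-repair genes, mirroring the functional
    composition the enrichment analysis assumes.
    """
    genes = list(_NAMED_PANEL_GENES[:n_genes])
    i = 1
    while len(genes) < n_genes:
        name = f"CG{i:04d}"
        if name not in genes:
            genes.append(name)
        i += 1
    epigenetic = {"KMT2C", "KMT2D", "ARID1A", "CREBBP", "EP300", "SETD2"} & set(genes)
    dna_repair = {"MLH1", "MSH2", "MSH6", "PMS2", "BRCA1", "BRCA2", "ATM", "POLE", "POLD1"} & set(genes)
    filler = [g for g in genes if g.startswith("CG")]
    idx = 0
    while len(epigenetic) < min(47, n_genes) and idx < len(filler):
        epigenetic.add(filler[idx])
        idx += 1
    while len(dna_repair) < min(45, n_genes) and idx < len(filler):
        dna_repair.add(filler[idx])
        idx += 1
    category = {g: {GeneCategory.epigenetic_regulation} for g in epigenetic}
    for g in dna_repair:
        category[g] = {GeneCategory.dna_repair}
    return GenePanel(genes=frozenset(genes), footprint_mb=footprint_mb, category=category)
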