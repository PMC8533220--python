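"""The published worked example: 22 discriminative tryptic peptides from
pancreatic-cancer tissue, with their prognostic feature, ROC AUC, LC-MS/MS
reference mass, signed deviation and parent protein.

The table below is the printed results table of the emulated study, embedded
verbatim as data (tab-separated).  The two pN AUC values keep their printed
decimal commas; :func:`msisig.msio.parse_number` normalizes them.  Rows
printed with a blank protein cell (continuation rows of a protein block)
carry the protein name explicitly here.

All peptide p-values were reported only as bounded, p < 0.001; the loader
materializes them as ``REPORTED_P`` (5e-4), strictly inside the bound, so the
records can pass through the numeric significance filter.  Signature counts
depend only on the bound, not on the materialized value.
"""

from __future__ import annotations

import io

import pandas as pd

from .annotate import ProteinAssignment, ReferencePeptide, infer_proteins, match_to_reference
from .discrim import DiscriminativeFeature, ScreenConfig, select_discriminative
from .msio import parse_number

__all__ = [
    "REPORTED_P",
    "load_worked_example",
    "reference_list",
    "discriminative_features",
    "reproduce_signatures",
]

REPORTED_P = 5e-4  # stands in for "p < 0.001"

_TABLE = """\
feature	msi_mz	auc	ref_mass	delta	protein
pL	1198.839	0.6005	1198.7052	0.1338	Actin, cytoplasmic 1
pL	1790.828	0.6128	1790.8874	-0.0594	Actin, cytoplasmic 1
pL	1547.791	0.6213	1547.7901	0.0009	Collagen alpha-2(I) chain
pL	1562.794	0.6343	1562.7900	0.0040	Collagen alpha-2(I) chain
pL	805.481	0.6001	805.4568	0.0242	Collagen alpha-3(VI) chain
pL	1467.68	0.6005	1467.7243	-0.0443	Collagen alpha-3(VI) chain
pL	1628.804	0.6099	1628.8466	-0.0426	Filamin-B
pL	1766.824	0.6078	1766.9417	-0.1177	Filamin-B
pL	1326.808	0.6125	1326.7631	0.0449	Histone H1.3
pL	2059.968	0.6056	2060.1222	-0.1542	Histone H1.3
pL	958.504	0.6056	958.5309	-0.0269	Spectrin beta chain, non-erythrocytic 1
pL	2059.068	0.6165	2059.1005	-0.0325	Spectrin beta chain, non-erythrocytic 1
pL	1690.913	0.6006	1690.8475	0.0655	Valosin-containing protein (VCP)
pL	1777.926	0.6156	1777.9513	-0.0253	Valosin-containing protein (VCP)
pL	1269.65	0.6235	1269.6794	-0.0294	Vinculin
pL	1428.674	0.6260	1428.7041	-0.0301	Vinculin
pN	831.585	0,3786	831.4925	0.0925	Histone H1.3
pN	1326.808	0,3985	1326.7631	0.0449	Histone H1.3
pV	1562.794	0.60311	1562.7900	0.0040	Collagen alpha-2(I) chain
pV	2026.963	0.6018	2027.0120	-0.0490	Collagen alpha-2(I) chain
pV	2056.067	0.6331	2056.0459	0.0211	Myosin-11
pV	2706.264	0.6078	2706.2320	0.0320	Myosin-11
"""


def load_worked_example() -> pd.DataFrame:
    """The worked-example table as a DataFrame with parsed numeric columns."""
    df = pd.read_csv(io.StringIO(_TABLE), sep="\t", dtype=str)
    for col in ("msi_mz", "auc", "ref_mass", "delta"):
        df[col] = df[col].map(parse_number)
    df["p_value"] = REPORTED_P
    return df


def reference_list() -> list[ReferencePeptide]:
    """The LC-MS/MS reference peptides of the worked example (deduplicated)."""
    df = load_worked_example()
    seen = set()
    refs = []
    for _, row in df.iterrows():
        key = (row["ref_mass"], row["protein"])
        if key not in seen:
            seen.add(key)
            refs.append(ReferencePeptide(mass=row["ref_mass"], protein=row["protein"]))
    return refs


def discriminative_features(feature: str) -> list[DiscriminativeFeature]:
    """The worked example's screened m/z records for one prognostic feature."""
    df = load_worked_example()
    block = df[df["feature"] == feature]
    if block.empty:
        raise ValueError(f"unknown feature {feature!r}")
    return [
        DiscriminativeFeature(
            mz=row["msi_mz"],
            auc=row["auc"],
            p_value=row["p_value"],
            direction="up" if row["auc"] > 0.5 else "down",
            feature=feature,
        )
        for _, row in block.iterrows()
    ]


def reproduce_signatures(
    tolerance: float = 0.2, min_peptides: int = 2
) -> dict[str, list[ProteinAssignment]]:
    """Run the discriminative filter, nearest-mass matching and the
    two-peptide concordance rule on the worked-example records.

    Returns per-feature protein assignments; with the published settings this
    yields 8 pL proteins (16 m/z), 1 pN protein (2 m/z, direction down) and
    2 pV proteins (4 m/z).
    """
    cfg = ScreenConfig()
    refs = reference_list()
    out: dict[str, list[ProteinAssignment]] = {}
    for feature in ("pL", "pN", "pV"):
        records = [
            (d.mz, d.auc, d.p_value) for d in discriminative_features(feature)
        ]
        selected = select_discriminative(records, cfg, feature=feature)
        matches = match_to_reference(selected, refs, tolerance=tolerance)
        out[feature] = infer_proteins(matches, min_peptides=min_peptides)
    return out
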