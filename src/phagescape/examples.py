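"""Worked-example data: tumor-selective peptide families grouped by their
elementary binding units.

These 9-mer peptides were recovered from a landscape phage library after one
pass of in vivo circulation in a breast-tumor xenograft model and grouped by
EBU network analysis.  They exercise the canonical network shapes: an isolated
motif (MYW), a simple chain of overlapping motifs (LMH/MHP/HPG, extending into
"LMHPG"), and a complex component around VGS with a contiguous branch
(VGS/AVS) and a variable-spacing branch (VGS/SEG).
"""

from __future__ import annotations

TUMOR_PEPTIDE_FAMILIES: dict[str, tuple[str, ...]] = {
    "MYW": (
        "AMYWDRASD",
        "DMYWDGASD",
        "DMYWDKASD",
        "DMYWDRADD",
        "DMYWDRALA",
        "DMYWDRALD",
        "DMYWDRAPD",
        "DMYWDRASA",
        "DMYWDRASD",
        "DMYWDRASG",
        "DMYWDSASD",
        "DMYWDSPSS",
        "DMYWGRASD",
        "GMYWDRASD",
        "VMYWDRASD",
        "YMYWDRASD",
    ),
    "LMH/MHP/HPG": (
        "DLMHGPVMD",
        "DLMHPGAAD",
        "DLMHPGAEG",
        "DLMHPGAID",
        "DLMHPGAKD",
        "DLMHPGAMA",
        "DLMHPGAMD",
        "DLMHPGAME",
        "DLMHPGAMG",
        "DLMHPGAMH",
        "DLMHPGAMN",
        "DLMHPGAMS",
        "DLMHPGAND",
        "DLMHPGASE",
        "DLMHPGATD",
        "GLMHPGAMD",
    ),
    "VGS/AVS": (
        "VGSAVSNEH",
        "VGSAVSSEH",
        "VTDVGSAVS",
    ),
    "VGS/SEG": (
        "ASVGSEGDL",
        "ASVGSEGST",
        "DPSLVGSEG",
        "DSSLVGSEG",
        "VGSEGMVID",
        "VGSEGSTTL",
        "VGSIQSEGT",
        "VGSTQSEGT",
    ),
}


def all_example_peptides() -> list[str]:
    """The full example pool, families concatenated (distinct peptides)."""
    out: list[str] = []
    for family in TUMOR_PEPTIDE_FAMILIES.values():
        out.extend(family)
    return out
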