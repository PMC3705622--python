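"""Per-locus clone-count tallies from strand-specific amplicon sequencing.

Ships a reference tally of plasmid-clone assignments in LNCaP cells (one
row per locus x strand x amplicon, ``clones`` of ``sequenced``) and helpers
to aggregate such tables by strand and amplicon set.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

ENV_AMPLICONS = ("env-1", "env-2", "env-3")


def load_clone_counts() -> pd.DataFrame:
    """The bundled LNCaP clone tally (columns locus, strand, amplicon,
    clones, sequenced)."""
    ref = resources.files("ervkit").joinpath("data/lncap_clone_counts.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def sum_strand_clones(
    counts: pd.DataFrame, strand: str, amplicons: tuple[str, ...] = ENV_AMPLICONS
) -> pd.Series:
    """Per-locus total clone counts on one strand over a set of amplicons."""
    sub = counts[(counts["strand"] == strand) & (counts["amplicon"].isin(amplicons))]
    return sub.groupby("locus")["clones"].sum().sort_values(ascending=False)
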