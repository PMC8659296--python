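"""Packaged fixture datasets.

Both fixtures are *synthetic stand-ins*, constructed to carry the structure
the analyses expect rather than measured values:

* ``amp_rpkm_synthetic.csv`` — a developmental RPKM table for 20 AMP
  transcripts in which drs, drsl2 and drsl5 dominate the pupariation (P0)
  peak and the remaining AMPs sit two to three orders of magnitude below;
* ``brz4_like_synthetic.pfm`` — an AT-rich 10-column position frequency
  matrix standing in for an ecdysone-response transcription-factor binding
  motif, in JASPAR text format.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from pupamp.io import PfmRecord, read_jaspar_pfm

AMP_FOCAL_TOP3 = ("drs", "drsl2", "drsl5")


def _data_path(name: str):
    return resources.files("pupamp") / "data" / name


def load_amp_rpkm() -> pd.DataFrame:
    """Synthetic developmental RPKM table, indexed by transcript."""
    with resources.as_file(_data_path("amp_rpkm_synthetic.csv")) as p:
        return pd.read_csv(p, index_col="transcript")


def load_brz4_like_pfm() -> PfmRecord:
    """Synthetic AT-rich binding-motif count matrix (JASPAR text format)."""
    with resources.as_file(_data_path("brz4_like_synthetic.pfm")) as p:
        return read_jaspar_pfm(p)
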