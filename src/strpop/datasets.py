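"""Bundled reference data: a published 21-locus STR frequency table.

The package ships the allele-frequency block and the printed per-locus
parameter rows of a published forensic population study of a Han
population sample (n = 275) from the Guanzhong region of Shaanxi, China,
typed at 21 non-CODIS autosomal STR loci.  Frequencies are printed to 4
decimals, so gene-copy counts are recovered as ``round(freq * 550)``;
the count-reconstructed, renormalized frequencies reproduce the printed
HE and PIC values exactly at 4 decimals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_frequency_csv
from .tables import AlleleFrequencyTable

__all__ = [
    "load_han_guanzhong_frequencies",
    "load_han_guanzhong_parameters",
    "HAN_GUANZHONG_N",
]

#: Typed individuals per locus in the bundled sample.
HAN_GUANZHONG_N = 275


def _data_path(name: str):
    return resources.files("strpop.data").joinpath(name)


def load_han_guanzhong_frequencies(count_reconstructed: bool = False) -> AlleleFrequencyTable:
    """The bundled 21-locus allele-frequency table (n = 275 per locus).

    With ``count_reconstructed=True``, frequencies are replaced by
    integer gene-copy counts recovered from the printed 4-decimal values
    (``round(f * 550) / 550``), which removes the print-rounding residue.
    """
    with resources.as_file(_data_path("han_guanzhong_21str_frequencies.csv")) as path:
        table = read_frequency_csv(path, "Han_Guanzhong", n=HAN_GUANZHONG_N)
    if count_reconstructed:
        for locus, freqs in table.frequencies.items():
            two_n = 2 * table.n[locus]
            table.frequencies[locus] = {
                allele: round(f * two_n) / two_n for allele, f in freqs.items()
            }
    return table


def load_han_guanzhong_parameters() -> pd.DataFrame:
    """The printed per-locus parameter rows (PD, PIC, PE, TPI, HO, HE, HWE p)."""
    with resources.as_file(_data_path("han_guanzhong_21str_parameters.csv")) as path:
        return pd.read_csv(path, index_col=0)
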