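"""Synthetic stand-in for the native microbial uricase sequence.

The real accession is not bundled; this module constructs a SYNTHETIC
302-residue sequence that reproduces the documented engineering landmarks
of the native enzyme so the sequence stages can be exercised end to end:

* exactly one integrin-binding RGD tripeptide, at positions 49-51;
* a single cysteine, inside the 11-residue C-terminal extension
  "HPIWSNIAGFC" that the engineering workflow removes;
* no other C, and no other RGD, anywhere.

It is a stand-in with the right features, not the real protein: identities
computed against it are meaningless, only the motif/truncation mechanics
are faithful.
"""

from __future__ import annotations

from .seqtools import ProteinSequence

__all__ = ["SYNTHETIC_URICASE", "CTERM_PEPTIDE", "RGD_POSITION"]

CTERM_PEPTIDE = "HPIWSNIAGFC"
RGD_POSITION = 49  # 1-based start of the single RGD motif

# Cys-free, RGD-free filler block (20 aa); R never directly precedes G
_FILLER = "AELKTVQDNSMHGIFPWYTR"


def _build() -> str:
    prefix = (_FILLER * 3)[:48]                      # residues 1-48
    body_len = 302 - len(CTERM_PEPTIDE) - 51         # residues 52-291
    body = (_FILLER * 15)[:body_len]
    seq = prefix + "RGD" + body + CTERM_PEPTIDE
    assert len(seq) == 302
    assert seq.count("C") == 1 and seq.endswith(CTERM_PEPTIDE)
    assert seq.find("RGD") == RGD_POSITION - 1 and seq.count("RGD") == 1
    return seq


SYNTHETIC_URICASE = ProteinSequence("uricase_synthetic_standin", _build())
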