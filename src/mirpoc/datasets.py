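"""Small curated tables used in worked examples and cross-checks.

``conditioning_regulation_flags`` transcribes the published qRT-PCR
significance calls (change versus the I/R group, p <= .05) for the left
ventricular mRNA panel of the rat post-conditioning responder study: which
of the three conditioned groups — pre-conditioning (IPC), post-conditioning
responders (IPoC-R) and non-responders (IPoC-NR) — significantly changed
each transcript. Feeding these flags to
:func:`mirpoc.patterns.classify_mrna_pattern` reproduces the published
group partition (3 genes regulated by all three conditionings, 3 by both
post-conditioning phenotypes but not IPC, 7 by responders and IPC).
"""

from __future__ import annotations

import pandas as pd

# gene -> (sig in IPoC-R, sig in IPoC-NR, sig in IPC); flags are the printed
# significance markers of the change versus the I/R group
_FLAGS = {
    # regulated by all three conditionings
    "Arrb2": (True, True, True),
    "Foxn3": (True, True, True),
    "Zbtb20": (True, True, True),
    # both post-conditioning phenotypes, not IPC
    "Efhd2": (True, True, False),
    "Grk2": (True, True, False),
    "Vegfa": (True, True, False),
    # responders and IPC, not non-responders
    "Col3a1": (True, False, True),
    "Eln": (True, False, True),
    "Psme3": (True, False, True),
    "Arg1": (True, False, True),
    "Casr": (True, False, True),
    "Bcl2": (True, False, True),
    "Adm2": (True, False, True),
    # responders only
    "Bgn": (True, False, False),
    "Col1a1": (True, False, False),
    "Nox2": (True, False, False),
    "Fn1": (True, False, False),
    "Jdp2": (True, False, False),
    "Tgfb1": (True, False, False),
    "Ramp1": (True, False, False),
    "Pthlh": (True, False, False),
    "Ramp3": (True, False, False),
    "Nos2": (True, False, False),
    "Arg2": (True, False, False),
    "Arrb1": (True, False, False),
    "Nos3": (True, False, False),
    "Ramp2": (True, False, False),
    "Grk5": (True, False, False),
    "Mdm2": (True, False, False),
    "Cxcl12": (True, False, False),
    "Oxsr1": (True, False, False),
    "Ppargc1b": (True, False, False),
    "Serca2a": (True, False, False),
    "Adrb2": (True, False, False),
    "Socs7": (True, False, False),
    # listed in the responder block but without a significance marker
    "Pln": (False, False, False),
}


def conditioning_regulation_flags() -> pd.DataFrame:
    """Published per-gene significance flags versus I/R (boolean columns
    ``IPoCR``, ``IPoCNR``, ``IPC``)."""
    df = pd.DataFrame.from_dict(_FLAGS, orient="index", columns=["IPoCR", "IPoCNR", "IPC"])
    df.index.name = "gene"
    return df


#: published study tallies used in worked examples: miRs read, miRs
#: differentially expressed on a raw-p screen, up/down after I/R, and
#: up-regulated miRs modified in post-conditioning responders
STUDY_MIR_COUNTS = {"read": 627, "de": 286, "up_ir": 82, "down_ir": 77, "up_modified_r": 23}

#: published load-free cell-shortening means (% of diastolic cell length)
#: before and after 24 h growth-factor treatment
CELL_SHORTENING = {"baseline": 10.30, "treated": 11.16}
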