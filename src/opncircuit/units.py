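"""Concentration unit conversion.

Serum assays report ng/mL; the circuit model works in nM throughout.
1 ng/mL = 1 ug/L, so  c[nM] = c[ng/mL] / MW[kDa].

Default molecular masses: recombinant OPN constructs ~35 kDa, the 20S
proteasome barrel ~700 kDa.
"""

OPN_KDA = 35.0
PROTEASOME_KDA = 700.0


def ng_ml_to_nm(conc_ng_ml, mw_kda: float):
    """Convert a mass concentration (ng/mL) to a molar one (nM)."""
    return conc_ng_ml / mw_kda


def nm_to_ng_ml(conc_nm, mw_kda: float):
    """Convert a molar concentration (nM) back to ng/mL."""
    return conc_nm * mw_kda
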