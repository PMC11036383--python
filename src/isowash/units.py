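"""Unit conversions at the package boundary.

Everything internal is SI (Pa, m, m3, kg, s). The lab-facing interfaces
speak mbar, mm, mL, um and g, so conversions live here and nowhere else.
"""

MBAR_TO_PA = 100.0
ML_TO_M3 = 1e-6
UM_TO_M = 1e-6
G_TO_KG = 1e-3
MM_TO_M = 1e-3


def mbar_to_pa(p_mbar: float) -> float:
    return p_mbar * MBAR_TO_PA


def pa_to_mbar(p_pa: float) -> float:
    return p_pa / MBAR_TO_PA


def ml_to_m3(v_ml: float) -> float:
    return v_ml * ML_TO_M3


def m3_to_ml(v_m3: float) -> float:
    return v_m3 / ML_TO_M3


def um_to_m(x_um: float) -> float:
    return x_um * UM_TO_M


def g_to_kg(m_g: float) -> float:
    return m_g * G_TO_KG


def kg_to_g(m_kg: float) -> float:
    return m_kg / G_TO_KG


def mm_to_m(x_mm: float) -> float:
    return x_mm * MM_TO_M
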