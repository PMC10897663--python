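"""Unit conversions.

All internal physics is SI (m, s, Pa, m^3/s); clinical units (mmHg, L/min,
cm, mm) appear only at I/O boundaries and in reported tables.
"""

MMHG_TO_PA = 133.322
LPM_TO_M3S = 1.0 / 60000.0


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def lpm_to_m3s(q_lpm: float) -> float:
    return q_lpm * LPM_TO_M3S


def m3s_to_lpm(q_m3s: float) -> float:
    return q_m3s / LPM_TO_M3S
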