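"""Unit conventions.

Everything internal is SI (Pa, m, N, kg/m^3).  Interface pressures cross the
package boundary in mmHg, the clinical convention for compression hosiery.
"""

PA_PER_MMHG = 133.322


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p_pa / PA_PER_MMHG
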