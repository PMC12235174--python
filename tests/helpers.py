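import numpy as np

from circalum.traces import TraceSeries


def make_cosine_trace(
    period: float = 24.0,
    peak_time: float = 6.0,
    mesor: float = 5.0,
    amplitude: float = 2.0,
    duration: float = 120.0,
    dt: float = 0.5,
    zt_offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TraceSeries:
    """y = mesor + amplitude*cos(2*pi*(t - peak_time)/period) (+ noise)."""
    t = np.arange(0.0, duration, dt)
    y = mesor + amplitude * np.cos(2 * np.pi * (t - peak_time) / period)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return TraceSeries(
        well_id="W0", strain="test", times=t, values=y,
        zt_offset=zt_offset, entrained_until=None,
    )
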