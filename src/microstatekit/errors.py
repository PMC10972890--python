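"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class NoPeakError(RuntimeError):
    """The model-order criterion curve has no interior local peak.

    Raised by :func:`microstatekit.cluster.select_k_optimal` when the KL
    series is monotone or otherwise peak-free; the remedy is usually a wider
    candidate-K grid.
    """
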