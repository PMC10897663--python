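"""Exception hierarchy for the archpwv pipeline."""


class ArchPWVError(Exception):
    """Base class for all archpwv-specific failures."""


class TuningError(ArchPWVError):
    """Mock-loop auto-tuning could not bring a pressure index into its window."""


class InsufficientDataError(ArchPWVError):
    """A record holds fewer complete cardiac cycles than required."""


class UnreliableEstimateError(ArchPWVError):
    """Cross-correlation peak too weak to trust the transit-time estimate."""


class ChannelError(ArchPWVError):
    """A waveform of the wrong channel (flow vs pressure) was supplied."""


class DegenerateDataError(ArchPWVError):
    """Input is degenerate for the requested statistic (e.g. constant matrix)."""
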