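"""Exception hierarchy for dataset validation and reporting."""


class EEGSelectError(Exception):
    """Base class for all package-specific errors."""


class DatasetError(EEGSelectError):
    """Base class for dataset layout/validation problems."""


class MissingManifestError(DatasetError):
    """The dataset directory has no manifest file."""


class EpochLengthError(DatasetError):
    """Epochs within one file disagree on sample count."""


class ChannelCountError(DatasetError):
    """An epoch's channel rows do not match the manifest montage."""


class EmptyFrontError(EEGSelectError):
    """A Pareto-front report was requested for an empty front."""


class CacheError(EEGSelectError):
    """Feature cache is incomplete or inconsistent with the dataset."""
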