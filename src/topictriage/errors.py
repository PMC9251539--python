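"""Exception hierarchy shared by all pipeline stages."""


class TopicTriageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TopicTriageError):
    """A configuration value or referenced column/parameter is invalid."""


class InputError(TopicTriageError):
    """Input data violates a documented contract (duplicate ids, bad labels...)."""


class ConsistencyError(TopicTriageError):
    """Two artifacts that must agree (topics vs. scores, metrics ranges) do not."""


class EmptyTopicError(TopicTriageError):
    """No word of a topic is present in the document-term matrix vocabulary."""

    def __init__(self, topic_id: str):
        self.topic_id = topic_id
        super().__init__(f"topic {topic_id!r} has no word in the matrix vocabulary")


class SplitError(TopicTriageError):
    """A stratified split cannot place at least one document of each class in both parts."""


class PipelineError(TopicTriageError):
    """A stage of the end-to-end workflow failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
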