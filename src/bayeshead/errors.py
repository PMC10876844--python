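"""Exception types shared across the package.

Invalid arguments raise plain :class:`ValueError` so callers can rely on the
standard idiom; the classes here mark conditions a pipeline may want to
handle distinctly from bad input.
"""


class DivergedTrainingError(RuntimeError):
    """Training produced a non-finite loss; carries the epoch it happened in."""

    def __init__(self, epoch: int, loss: float):
        self.epoch = epoch
        self.loss = loss
        super().__init__(f"non-finite training loss ({loss!r}) in epoch {epoch}")


class EmptySubsetError(RuntimeError):
    """A metric was requested on an empty sample subset.

    Distinct from ValueError so a threshold sweep can skip-and-flag the row
    instead of aborting.
    """


class FormatError(RuntimeError):
    """A file on disk could not be parsed in its declared format."""
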