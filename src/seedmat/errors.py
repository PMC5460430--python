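"""Exception types shared across the package."""


class SeedmatError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(SeedmatError):
    """A character could not be canonicalized under the active policy."""


class RaggedAlignmentError(SeedmatError):
    """Rows of one alignment record have unequal lengths."""


class NoRecordsError(SeedmatError):
    """An input file contained no alignment records."""


class AllGapSequenceError(SeedmatError):
    """Similarity is undefined for a sequence with no residues."""


class MatrixFormatError(SeedmatError):
    """A substitution-matrix text file violates the square-table dialect."""


class ZeroCellError(SeedmatError):
    """A canonical pair frequency is zero, so its log-odds score is undefined."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        shown = ", ".join(f"{a}-{b}" for a, b in self.pairs[:10])
        more = "" if len(self.pairs) <= 10 else f" (+{len(self.pairs) - 10} more)"
        super().__init__(
            f"{len(self.pairs)} canonical pair(s) were never observed: {shown}{more}. "
            "Raise the clustering threshold, add more alignments, or pass a pseudocount."
        )


class ZeroObservationsError(SeedmatError):
    """A group contributed no residue pairs (N_k = 0)."""
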