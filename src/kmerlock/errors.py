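"""Exception types shared across the package."""


class KmerlockError(Exception):
    """Base class for all package-specific errors."""


class EncodingError(KmerlockError):
    """A sequence contains symbols outside {A, C, G, T} or has a bad length."""


class PanelDesignError(KmerlockError):
    """A panel cannot satisfy the requested distinctness conditions."""


class NoiseBudgetExhausted(KmerlockError):
    """A homomorphic operation would push the noise past the decryptable bound."""


class MissingRotationKey(KmerlockError):
    """A slot rotation was requested for an amount with no key-switch material."""


class ParameterMismatch(KmerlockError):
    """Ciphertexts and key material were created under different parameters."""
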