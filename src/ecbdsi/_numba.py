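"""Optional numba acceleration.

All numerical kernels are written as plain scalar/array Python functions and
decorated with :func:`njit`.  When numba is importable the kernels are compiled
(with on-disk caching); otherwise they run as ordinary Python, which is only
practical for very short integrations.
"""

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _numba_njit

    HAVE_NUMBA = True

    def njit(func=None, **kwargs):
        kwargs.setdefault("cache", True)
        kwargs.setdefault("fastmath", False)
        if func is None:
            return _numba_njit(**kwargs)
        return _numba_njit(**kwargs)(func)

except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(func=None, **kwargs):
        if func is None:
            return lambda f: f
        return func
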