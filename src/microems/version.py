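"""Version and provenance helpers."""

__version__ = "0.1.0"


def provenance_line(**meta) -> str:
    """One '#'-prefixed provenance comment for text outputs."""
    parts = [f"microems v{__version__}"]
    parts += [f"{k}={v}" for k, v in sorted(meta.items())]
    return "# " + " ".join(parts) + "\n"
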