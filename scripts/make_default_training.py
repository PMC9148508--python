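"""Regenerate the packaged default training data.

The distribution ships a synthetic training set
(``src/fragscan/data/train_synthetic``): emission tables drawn from a
fixed seed with a mild codon-usage sharpness, tilted per GC bin so
G/C-rich bins prefer G/C bases, in-frame stop codons suppressed, and
boundary tables peaked on the canonical start/stop codons.  It stands
in for a model trained on annotated genomes and is clearly labelled as
synthetic; anyone with a real FGS-format training directory can point
the tool at it with ``-r``.

Run from the repository root:

    python scripts/make_default_training.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from fragscan.fixtures import _pwm_block, _comp_reverse_pwm, _suppress_inframe_stops
from fragscan.model import BinParams, HmmParams, _log, write_training_set

SEED = 20240601
BIN_LO, BIN_HI = 42, 58
STRENGTH = 2.0
WINDOW = 9
PEAK = 0.85

#: per-base indel rates by condition: <platform>_<errors per kb> maps to
#: rate/2 insertions and rate/2 deletions per base.
CONDITIONS = {
    "complete": 0.00002,
    "sanger_5": 0.005,
    "sanger_10": 0.010,
    "454_10": 0.010,
    "454_30": 0.030,
    "illumina_5": 0.005,
    "illumina_10": 0.010,
}

SHARED_RATES = {
    "noncoding_to_gene": 1e-3,
    "gene_to_stop": 0.01,
    "insert_continue": 0.1,
}


def rates_for(indel_rate: float) -> dict[str, float]:
    return dict(
        SHARED_RATES,
        match_to_insert=indel_rate / 2.0,
        match_skip=indel_rate / 2.0,
    )


def tilted_tables(rng: np.random.Generator, gc_pct: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward/reverse match tables and a noncoding table for one bin."""
    tilt = (gc_pct - 50) / 50.0  # logit shift toward G/C for GC-rich bins
    shift = tilt * np.array([-1.0, 1.0, 1.0, -1.0])  # A C G T
    fwd = np.exp(STRENGTH * rng.standard_normal((6, 16, 4)) + shift)
    rev = np.exp(STRENGTH * rng.standard_normal((6, 16, 4)) + shift)
    fwd /= fwd.sum(axis=-1, keepdims=True)
    rev /= rev.sum(axis=-1, keepdims=True)
    _suppress_inframe_stops(fwd, rev, 4.0)
    nc = np.exp(0.3 * rng.standard_normal((4, 4)) + 0.5 * shift)
    nc /= nc.sum(axis=-1, keepdims=True)
    return fwd, rev, nc


def main() -> None:
    rng = np.random.default_rng(SEED)
    start_pwm = _pwm_block(("ATG", "GTG", "TTG"), PEAK, WINDOW)
    stop_pwm = _pwm_block(("TAA", "TAG", "TGA"), PEAK, WINDOW)
    adjust = {k: (0.0, 0.0, 1.0) for k in ("start", "stop", "rev_start", "rev_stop")}

    gc_bins = {}
    for label in range(BIN_LO, BIN_HI + 1):
        fwd, rev, nc = tilted_tables(rng, label)
        gc_bins[label] = BinParams(
            match_emissions=_log(fwd),
            rev_match_emissions=_log(rev),
            noncoding_emissions=_log(nc),
            start_pwm=_log(start_pwm),
            stop_pwm=_log(stop_pwm),
            rev_start_pwm=_log(_comp_reverse_pwm(start_pwm)),
            rev_stop_pwm=_log(_comp_reverse_pwm(stop_pwm)),
            boundary_adjust=dict(adjust),
        )

    params = HmmParams(
        gc_bins=gc_bins,
        condition_name="complete",
        rates=rates_for(CONDITIONS["complete"]),
    )
    dest = Path(__file__).resolve().parent.parent / "src" / "fragscan" / "data" / "train_synthetic"
    write_training_set(
        params,
        dest,
        fmt="%.6f",
        conditions={name: rates_for(rate) for name, rate in CONDITIONS.items()},
    )
    (dest / "PROVENANCE").write_text(
        "Synthetic default training data generated by scripts/make_default_training.py\n"
        f"(seed {SEED}); not trained on real genomes. Substitute a real FGS-format\n"
        "training directory with the -r option for production use.\n",
        encoding="ascii",
    )
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
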