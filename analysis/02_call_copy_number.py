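#!/usr/bin/env python
"""Copy-number karyotyping of the simulated embryos.

Normalizes the binned counts, segments each profile, calls integer/mosaic
copy numbers, serializes karyotype strings, and classifies each embryo as
euploid, reference (unbalanced on both translocation chromosomes) or other.
Prints one line per embryo; results accumulate in results/work/state.pkl.
"""
import sys
from pathlib import Path

from click.testing import CliRunner

from pgtsr.cli import main as cli

OUT = Path(__file__).resolve().parent.parent / "results" / "work"


def run() -> None:
    res = CliRunner().invoke(cli, ["cnv", str(OUT)])
    sys.stdout.write(res.output)
    if res.exit_code:
        raise SystemExit(res.exit_code)


if __name__ == "__main__":
    run()
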