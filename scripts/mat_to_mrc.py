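#!/usr/bin/env python
"""Convert a MATLAB .mat array (volume or tilt-series stack) to MRC2014.

Convenience converter for datasets distributed as MATLAB files.  Picks the
first non-metadata variable unless --var is given; 3D arrays are written
as-is, 2D arrays as single-section volumes.

Usage:
    python scripts/mat_to_mrc.py input.mat output.mrc [--var NAME]
"""

import argparse

import numpy as np
from scipy.io import loadmat

from resire.mrc import write_mrc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("mat_path")
    ap.add_argument("mrc_path")
    ap.add_argument("--var", default=None, help="variable name inside the .mat file")
    args = ap.parse_args()

    data = loadmat(args.mat_path)
    names = [k for k in data if not k.startswith("__")]
    if not names:
        raise SystemExit(f"{args.mat_path}: no data variables found")
    name = args.var or names[0]
    if name not in data:
        raise SystemExit(f"{args.mat_path}: no variable {name!r}; available: {names}")
    arr = np.asarray(data[name], dtype=np.float32)
    if arr.ndim not in (2, 3):
        raise SystemExit(f"variable {name!r} has shape {arr.shape}; need 2D or 3D")
    write_mrc(args.mrc_path, arr)
    print(f"wrote {name} {arr.shape} -> {args.mrc_path}")


if __name__ == "__main__":
    main()
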