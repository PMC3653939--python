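#!/usr/bin/env python
"""Temporal trends of the limitation components.

Correlates the strength of each limitation component, evaluated at
ambient seed input from each census's fitted model, against census
month (Pearson r with a t test on n-2 df).  Declining seed limitation
with constant-or-rising density dependence reproduces the qualitative
ontogenetic pattern the decomposition is designed to expose.
"""

import argparse
import json

import numpy as np
import pandas as pd

from seedlim.limitation import temporal_trend

parser = argparse.ArgumentParser()
parser.add_argument("--out", default="results/trends.json")
args = parser.parse_args()

fits = json.load(open("results/fits.json"))
months = sorted(int(m) for m in fits)
trends = {}
for name in ("L_S", "L_DI", "L_DD", "L_E"):
    values = []
    for m in months:
        curve = pd.read_csv(f"results/limitation_{m:02d}.csv")
        amb = curve.S.iloc[0] / curve.ambient_multiple.iloc[0]
        values.append(float(np.interp(amb, curve.S, curve[name])))
    tr = temporal_trend(values, months, quantity=name)
    trends[name] = {"values": values, "r": tr.pearson_r, "t": tr.t_stat,
                    "df": tr.df, "p": tr.p_value}
    sig = "significant" if tr.p_value < 0.05 else "not significant"
    print(f"{name}: r = {tr.pearson_r:+.3f}, t = {tr.t_stat:+.2f}, "
          f"df = {tr.df}, p = {tr.p_value:.4f} ({sig})")

with open(args.out, "w") as fh:
    json.dump(trends, fh, indent=2, sort_keys=True)
print(f"wrote {args.out}")
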