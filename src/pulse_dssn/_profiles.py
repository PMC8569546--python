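"""Calibrated class-profile constants (generated file).

Regenerated by ``scripts/calibrate_profiles.py``, which tunes the main-wave
amplitude, centre and falling-flank width of each class so that the package's
own feature extractor recovers the reference per-class means of h1, k, w and
w/T.  Do not edit the numbers by hand; rerun the script instead.
"""

from .simulate import ClassProfile, ComponentWave

# fmt: off
_RAW = {
    # cid: (name, amp1, c1, s1l, s1r, a2rel, c2, s2, a3rel, c3, s3,
    #       T_mean, amp_rel_sd, target (h1, k, w, w/T) mean/sd pairs)
    1: ('slippery',           609.300, 0.16624, 0.04950, 0.11575,
        0.30, 0.380, 0.050, 0.24, 0.600, 0.060,
        0.7778, 0.339,
        ((610.701, 206.724), (6.609, 2.241), (0.126, 0.018), (0.162, 0.023))),
    2: ('flat',               514.801, 0.14107, 0.04204, 0.12378,
        0.34, 0.370, 0.050, 0.22, 0.620, 0.065,
        0.8667, 0.236,
        ((514.706, 121.698), (5.886, 1.394), (0.143, 0.031), (0.165, 0.036))),
    3: ('thready',            400.019, 0.16464, 0.04905, 0.17722,
        0.25, 0.460, 0.055, 0.24, 0.680, 0.065,
        0.9299, 0.348,
        ((400.857, 139.692), (3.662, 1.161), (0.199, 0.034), (0.214, 0.035))),
    4: ('stringy',            590.430, 0.16563, 0.04936, 0.22216,
        0.22, 0.520, 0.050, 0.22, 0.730, 0.060,
        0.8449, 0.386,
        ((592.404, 228.413), (5.919, 2.543), (0.207, 0.044), (0.245, 0.038))),
    5: ('thready-slippery',   356.595, 0.16859, 0.05021, 0.13363,
        0.31, 0.400, 0.050, 0.23, 0.620, 0.060,
        0.7568, 0.263,
        ((356.757, 93.869), (3.912, 1.002), (0.14, 0.03), (0.185, 0.04))),
    6: ('thready-stringy',    406.331, 0.17360, 0.05173, 0.21642,
        0.22, 0.510, 0.050, 0.23, 0.720, 0.060,
        0.8300, 0.387,
        ((407.703, 157.803), (3.957, 1.468), (0.205, 0.043), (0.247, 0.038))),
    7: ('stringy-slippery',   635.070, 0.17591, 0.05240, 0.18198,
        0.24, 0.470, 0.050, 0.24, 0.680, 0.060,
        0.8000, 0.357,
        ((636.707, 227.226), (6.329, 2.42), (0.176, 0.036), (0.22, 0.033))),
}
# fmt: on


def _build() -> dict[int, ClassProfile]:
    profiles = {}
    for cid, row in _RAW.items():
        (name, amp1, c1, s1l, s1r, a2rel, c2, s2, a3rel, c3, s3,
         t_mean, amp_rel_sd, targets) = row
        main = ComponentWave(amp=amp1, center=c1, width_left=s1l, width_right=s1r)
        tidal = ComponentWave(amp=a2rel * amp1, center=c2, width_left=s2, width_right=s2)
        dicrotic = ComponentWave(amp=a3rel * amp1, center=c3, width_left=s3, width_right=s3)
        profiles[cid] = ClassProfile(
            class_id=cid,
            class_name=name,
            component_params=(main, tidal, dicrotic),
            period_mean_s=t_mean,
            period_sd_s=0.04 * t_mean,
            amp_rel_sd=amp_rel_sd,
            target_stats={
                "h1": targets[0],
                "k": targets[1],
                "w": targets[2],
                "w_over_T": targets[3],
            },
        )
    return profiles


PROFILES: dict[int, ClassProfile] = _build()
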