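"""Score emotional contagion between an induced state and face judgments.

Builds a few affective coordinates by hand and prints their contagion
scores: 1 means the judged face affect coincides with the rater's own
induced state (total contagion), 0 means the two are at opposite corners
of the 0-100 negativity/positivity/arousal space.
"""

from affectcontagion import contagion_score

# A participant who just watched an upsetting clip: high negativity and
# arousal, low positivity.
induced_state = (80.0, 10.0, 70.0)

faces = {
    "angry face, judged very negative": (75.0, 12.0, 65.0),
    "angry face, judged moderately negative": (60.0, 25.0, 50.0),
    "happy face, judged positive": (10.0, 80.0, 40.0),
}

print(f"induced state (neg, pos, aro) = {induced_state}\n")
for label, judgment in faces.items():
    score = contagion_score(induced_state, judgment)
    print(f"{label:42s} ec = {score:.3f}")

print(
    "\nHigher scores mean the face judgment sits closer to the rater's own"
    "\ninduced state, i.e. more affect leaked into the judgment."
)
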