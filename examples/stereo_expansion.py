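"""R/S enumeration at fragment joining atoms.

A fragment whose first (joining) atom carries a defined tetrahedral tag is
expanded into both parity configurations; untagged or non-stereogenic
joining atoms pass through unchanged.  A 13-motif library with 11 defined
joining stereocenters therefore becomes 24 choices, and 7 all-defined
sugars become 14.
"""

from macroforge import (
    Fragment,
    FragmentKind,
    ToyLibrarySpec,
    classify_join_stereo,
    expand_fragment_stereocenters,
    expand_library,
    make_toy_fragments,
)

for body in ["[C@H](C)O", "C(C)", "C(F)CC"]:
    frag = Fragment(
        id="SM001", kind=FragmentKind.SM, body=body,
        join_stereo=classify_join_stereo(body),
    )
    result = expand_fragment_stereocenters(frag)
    print(f"{body!r:16} {frag.join_stereo.value:10} -> "
          f"{[v.body for v in result.variants]}")

sms = make_toy_fragments(ToyLibrarySpec(13, 11, "SM"))
sugars = make_toy_fragments(ToyLibrarySpec(7, 7, "SUGAR"))
print(f"13 SMs (11 with defined joins) expand to {len(expand_library(sms))}")
print(f"7 sugars (all defined) expand to {len(expand_library(sugars))}")
# Both configurations are always generated: no CIP assignment is attempted,
# since which configuration is biosynthetically accessible is unresolved.
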