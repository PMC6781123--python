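"""Build a numerator relationship matrix by the tabular method.

Shows the textbook relationships (full sibs 0.5, parent-offspring 0.5,
selfing f = 0.5) and the status-number effective size of a group.
"""

import pandas as pd

from treegs import Pedigree, build_A, status_number

ped = Pedigree.from_records([
    ("A", None, None),
    ("B", None, None),
    ("C", "A", "B"),     # full sibs C, D
    ("D", "A", "B"),
    ("E", "C", "D"),     # full-sib mating -> inbred
    ("S", "A", "A"),     # selfed offspring of A
])
rm = build_A(ped)

print(pd.DataFrame(rm.A, index=rm.ids, columns=rm.ids).round(3))
print()
print("inbreeding:", dict(zip(rm.ids, rm.f.round(3))))
print(f"status number of (C, D, E, S): {status_number(rm, ['C', 'D', 'E', 'S']):.2f}")

# A[C,D] = 0.5 (full sibs); E's inbreeding is 0.25 (parents are full sibs);
# S's is 0.5 (selfing). The status number of the offspring group is far
# below 4 because they all descend from the same two founders.
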