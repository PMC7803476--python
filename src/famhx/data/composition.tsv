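# Disambiguation (relative-of-relative) rules: outer relative <TAB> inner
# relative <TAB> resolved relative <TAB> resolved side.
# Side values: Maternal, Paternal, NA, or Inherit (copy the outer mention's
# side, e.g. maternal aunt's son -> maternal cousin).  Pairs absent from
# this table fall back to (inner, NA).
Father	Father	Grandfather	Paternal
Father	Mother	Grandmother	Paternal
Father	Parent	Grandparent	Paternal
Father	Brother	Uncle	Paternal
Father	Sister	Aunt	Paternal
Father	Sibling	Uncle	Paternal
Father	Son	Brother	NA
Father	Daughter	Sister	NA
Father	Child	Sibling	NA
Father	Uncle	GreatUncle	Paternal
Father	Aunt	GreatAunt	Paternal
Father	Grandfather	GreatGrandfather	Paternal
Father	Grandmother	GreatGrandmother	Paternal
Father	Grandparent	GreatGrandparent	Paternal
Father	Cousin	Cousin	Paternal
Mother	Father	Grandfather	Maternal
Mother	Mother	Grandmother	Maternal
Mother	Parent	Grandparent	Maternal
Mother	Brother	Uncle	Maternal
Mother	Sister	Aunt	Maternal
Mother	Sibling	Uncle	Maternal
Mother	Son	Brother	NA
Mother	Daughter	Sister	NA
Mother	Child	Sibling	NA
Mother	Uncle	GreatUncle	Maternal
Mother	Aunt	GreatAunt	Maternal
Mother	Grandfather	GreatGrandfather	Maternal
Mother	Grandmother	GreatGrandmother	Maternal
Mother	Grandparent	GreatGrandparent	Maternal
Mother	Cousin	Cousin	Maternal
Parent	Father	Grandfather	NA
Parent	Mother	Grandmother	NA
Parent	Parent	Grandparent	NA
Parent	Brother	Uncle	NA
Parent	Sister	Aunt	NA
Parent	Sibling	Uncle	NA
Parent	Son	Brother	NA
Parent	Daughter	Sister	NA
Parent	Child	Sibling	NA
Grandfather	Father	GreatGrandfather	Inherit
Grandfather	Mother	GreatGrandmother	Inherit
Grandfather	Brother	GreatUncle	Inherit
Grandfather	Sister	GreatAunt	Inherit
Grandfather	Son	Uncle	Inherit
Grandfather	Daughter	Aunt	Inherit
Grandmother	Father	GreatGrandfather	Inherit
Grandmother	Mother	GreatGrandmother	Inherit
Grandmother	Brother	GreatUncle	Inherit
Grandmother	Sister	GreatAunt	Inherit
Grandmother	Son	Uncle	Inherit
Grandmother	Daughter	Aunt	Inherit
Grandparent	Father	GreatGrandfather	Inherit
Grandparent	Mother	GreatGrandmother	Inherit
Grandparent	Parent	GreatGrandparent	Inherit
Grandparent	Brother	GreatUncle	Inherit
Grandparent	Sister	GreatAunt	Inherit
Grandparent	Son	Uncle	Inherit
Grandparent	Daughter	Aunt	Inherit
Uncle	Son	Cousin	Inherit
Uncle	Daughter	Cousin	Inherit
Uncle	Child	Cousin	Inherit
Uncle	Partner	Aunt	Inherit
Aunt	Son	Cousin	Inherit
Aunt	Daughter	Cousin	Inherit
Aunt	Child	Cousin	Inherit
Aunt	Partner	Uncle	Inherit
Brother	Son	Nephew	NA
Brother	Daughter	Niece	NA
Brother	Child	Nephew	NA
Sister	Son	Nephew	NA
Sister	Daughter	Niece	NA
Sister	Child	Nephew	NA
Sibling	Son	Nephew	NA
Sibling	Daughter	Niece	NA
Sibling	Child	Nephew	NA
Son	Son	Grandson	NA
Son	Daughter	Granddaughter	NA
Son	Child	Grandchild	NA
Daughter	Son	Grandson	NA
Daughter	Daughter	Granddaughter	NA
Daughter	Child	Grandchild	NA
Child	Son	Grandson	NA
Child	Daughter	Granddaughter	NA
Child	Child	Grandchild	NA
Cousin	Son	ThirdDegreeCousin	NA
Cousin	Daughter	ThirdDegreeCousin	NA
Cousin	Child	ThirdDegreeCousin	NA
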