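# surface <TAB> canonical relation <TAB> implied side (NA unless the surface itself implies one)
# The lexicon includes plural forms and colloquial variants, plus extended
# relatives (partner terms, nephew, great-grandparents, half-relations) so
# cascades and partner branches resolve before eligibility filtering.
father	Father	NA
fathers	Father	NA
dad	Father	NA
daddy	Father	NA
papa	Father	NA
mother	Mother	NA
mothers	Mother	NA
mom	Mother	NA
mum	Mother	NA
mama	Mother	NA
parent	Parent	NA
parents	Parent	NA
brother	Brother	NA
brothers	Brother	NA
sister	Sister	NA
sisters	Sister	NA
son	Son	NA
sons	Son	NA
daughter	Daughter	NA
daughters	Daughter	NA
child	Child	NA
children	Child	NA
kid	Child	NA
kids	Child	NA
grandfather	Grandfather	NA
grandfathers	Grandfather	NA
grandpa	Grandfather	NA
granddad	Grandfather	NA
grandmother	Grandmother	NA
grandmothers	Grandmother	NA
grandma	Grandmother	NA
granny	Grandmother	NA
grandparent	Grandparent	NA
grandparents	Grandparent	NA
maternal grandfather	Grandfather	Maternal
paternal grandfather	Grandfather	Paternal
maternal grandmother	Grandmother	Maternal
paternal grandmother	Grandmother	Paternal
cousin	Cousin	NA
cousins	Cousin	NA
sibling	Sibling	NA
siblings	Sibling	NA
uncle	Uncle	NA
uncles	Uncle	NA
aunt	Aunt	NA
aunts	Aunt	NA
auntie	Aunt	NA
# --- extended relatives: recognized, then filtered as ineligible ---
nephew	Nephew	NA
nephews	Nephew	NA
niece	Niece	NA
nieces	Niece	NA
great grandfather	GreatGrandfather	NA
great grandfathers	GreatGrandfather	NA
great grandmother	GreatGrandmother	NA
great grandmothers	GreatGrandmother	NA
great grandparent	GreatGrandparent	NA
great grandparents	GreatGrandparent	NA
great aunt	GreatAunt	NA
great aunts	GreatAunt	NA
great uncle	GreatUncle	NA
great uncles	GreatUncle	NA
half brother	HalfBrother	NA
half brothers	HalfBrother	NA
half sister	HalfSister	NA
half sisters	HalfSister	NA
half sibling	HalfSibling	NA
half siblings	HalfSibling	NA
half uncle	HalfUncle	NA
half uncles	HalfUncle	NA
half aunt	HalfAunt	NA
grandson	Grandson	NA
grandsons	Grandson	NA
granddaughter	Granddaughter	NA
granddaughters	Granddaughter	NA
grandchild	Grandchild	NA
grandchildren	Grandchild	NA
stepfather	Stepfather	NA
stepmother	Stepmother	NA
stepbrother	Stepsibling	NA
stepsister	Stepsibling	NA
# --- partner terms: head a partner branch, never eligible output ---
wife	Partner	NA
husband	Partner	NA
partner	Partner	NA
spouse	Partner	NA
ex wife	Partner	NA
ex husband	Partner	NA
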