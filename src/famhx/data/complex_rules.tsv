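# Complex family-member rules, applied to the cleaned sentence in file
# order (first match wins).  Six parts per rule:
# keyword <TAB> before terms (comma-separated, in order) <TAB> after terms
# <TAB> action (Keep|Discard) <TAB> relative <TAB> side
# Keep rules emit the stated relative; Discard rules suppress the keyword's
# mention (e.g. a father's "children" are the patient's half-siblings and
# must not be annotated as Child).
grandparents	patients,paternal		Keep	Grandparent	Paternal
grandparents	patients,maternal		Keep	Grandparent	Maternal
grandparent	patients,paternal		Keep	Grandparent	Paternal
grandparent	patients,maternal		Keep	Grandparent	Maternal
grandmother	patients,paternal		Keep	Grandmother	Paternal
grandmother	patients,maternal		Keep	Grandmother	Maternal
grandfather	patients,paternal		Keep	Grandfather	Paternal
grandfather	patients,maternal		Keep	Grandfather	Maternal
grandma	patients,paternal		Keep	Grandmother	Paternal
grandma	patients,maternal		Keep	Grandmother	Maternal
grandpa	patients,paternal		Keep	Grandfather	Paternal
grandpa	patients,maternal		Keep	Grandfather	Maternal
aunt	patients,paternal		Keep	Aunt	Paternal
aunt	patients,maternal		Keep	Aunt	Maternal
aunts	patients,paternal		Keep	Aunt	Paternal
aunts	patients,maternal		Keep	Aunt	Maternal
uncle	patients,paternal		Keep	Uncle	Paternal
uncle	patients,maternal		Keep	Uncle	Maternal
uncles	patients,paternal		Keep	Uncle	Paternal
uncles	patients,maternal		Keep	Uncle	Maternal
cousin	patients,paternal		Keep	Cousin	Paternal
cousin	patients,maternal		Keep	Cousin	Maternal
cousins	patients,paternal		Keep	Cousin	Paternal
cousins	patients,maternal		Keep	Cousin	Maternal
grandparents	patients		Keep	Grandparent	NA
children	father		Discard	Child	NA
children	mother		Discard	Child	NA
children	brother		Discard	Child	NA
children	sister		Discard	Child	NA
children	aunt		Discard	Child	NA
children	uncle		Discard	Child	NA
siblings	father		Discard	Sibling	NA
siblings	mother		Discard	Sibling	NA
kids	father		Discard	Child	NA
kids	mother		Discard	Child	NA
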