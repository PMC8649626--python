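# Default mapping from DHS hv101 "relationship to household head" labels to
# the 13 canonical roster categories.  Raw labels are matched case-insensitively
# after stripping surrounding whitespace.  Survey-specific label sets can be
# supplied as a file of the same shape.
strict: true
dhs_weight_scale: false
married_statuses:
  - married
  - living with partner
  - living together
map:
  HEAD: head
  WIFE OR HUSBAND: wife_or_husband
  HUSBAND OR WIFE: wife_or_husband
  WIFE: wife_or_husband
  HUSBAND: wife_or_husband
  SPOUSE: wife_or_husband
  SON/DAUGHTER: son_or_daughter
  SON OR DAUGHTER: son_or_daughter
  SON: son_or_daughter
  DAUGHTER: son_or_daughter
  CHILD: son_or_daughter
  SON/DAUGHTER-IN-LAW: son_or_daughter_in_law
  SON OR DAUGHTER IN LAW: son_or_daughter_in_law
  SON-IN-LAW OR DAUGHTER-IN-LAW: son_or_daughter_in_law
  SON-IN-LAW: son_or_daughter_in_law
  DAUGHTER-IN-LAW: son_or_daughter_in_law
  PARENT: parent
  FATHER/MOTHER: parent
  FATHER OR MOTHER: parent
  PARENT-IN-LAW: parent_in_law
  FATHER/MOTHER-IN-LAW: parent_in_law
  FATHER OR MOTHER IN LAW: parent_in_law
  BROTHER/SISTER: sibling
  BROTHER OR SISTER: sibling
  SIBLING: sibling
  GRANDPARENT: grandparent
  GRANDFATHER/GRANDMOTHER: grandparent
  GRANDCHILD: grandchild
  GRANDSON/GRANDDAUGHTER: grandchild
  ADOPTED/FOSTER/STEPCHILD: adopted_child
  ADOPTED CHILD: adopted_child
  FOSTER CHILD: adopted_child
  STEPCHILD: adopted_child
  # Kin with no dedicated canonical category are pooled into other_relative;
  # their dyads resolve to "other", which can never create an in-law link.
  OTHER RELATIVE: other_relative
  NIECE/NEPHEW: other_relative
  NIECE/NEPHEW BY BLOOD: other_relative
  NIECE/NEPHEW BY MARRIAGE: other_relative
  CO-SPOUSE: other_relative
  NOT RELATED: not_related
  DOMESTIC EMPLOYEE: not_related
  OTHER: other
  DK: other
  DON'T KNOW: other
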