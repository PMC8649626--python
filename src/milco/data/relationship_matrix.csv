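index_rel,head,wife_or_husband,son_or_daughter,son_or_daughter_in_law,parent,parent_in_law,sibling,grandparent,grandchild,adopted_child,other_relative,not_related,other
head,self,spouse,parent,parent_in_law,child,child_in_law,sibling,grandchild,grandparent,other,other,other,other
wife_or_husband,spouse,self,parent,parent_in_law,child_in_law,child,sibling_in_law,grandchild,grandparent,other,other,other,other
son_or_daughter,child,child,sibling,spouse_or_sibling_in_law,grandchild,grandchild,niece_nephew,other,parent_or_aunt_uncle,other,other,other,other
son_or_daughter_in_law,child_in_law,child_in_law,spouse_or_sibling_in_law,sibling_in_law,grandchild_in_law,grandchild_in_law,niece_nephew_in_law,other,parent_or_aunt_uncle,other,other,other,other
parent,parent,parent_in_law,grandparent,grandparent_in_law,spouse,co_in_law,parent,other,great_grandchild,other,other,other,other
parent_in_law,parent_in_law,parent,grandparent,grandparent_in_law,co_in_law,spouse_or_both_parents_in_law,other_in_law,other,great_grandparent,other,other,other,other
sibling,sibling,sibling_in_law,aunt_uncle,aunt_uncle_in_law,child,other_in_law,sibling,other,great_aunt_uncle,other,other,other,other
grandparent,grandparent,grandparent,other,other,other,other,other,other,other,other,other,other,other
grandchild,grandchild,grandchild,parent_or_aunt_uncle,parent_or_aunt_uncle,great_grandchild,great_grandchild,great_niece_nephew,other,sibling_or_cousin,other,other,other,other
adopted_child,other,other,other,other,other,other,other,other,other,other,other,other,other
other_relative,other,other,other,other,other,other,other,other,other,other,other,other,other
not_related,other,other,other,other,other,other,other,other,other,other,other,other,other
other,other,other,other,other,other,other,other,other,other,other,other,other,other
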