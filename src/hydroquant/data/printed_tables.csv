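table_id,row_label,col_label,count,note
eh_presence_all,EH present,VM,2,"2/25 with EH, all VM"
eh_presence_all,EH present,MD,23,"23/29 with EH, all MD"
eh_presence_all,EH present,VM-MD,2,"2/8 with EH, overlap group"
eh_presence_all,EH absent,VM,23,complement of 2/25
eh_presence_all,EH absent,MD,6,complement of 23/29
eh_presence_all,EH absent,VM-MD,6,complement of 2/8
eh_presence_definite,EH present,VM,1,"1/19 with EH, definite VM"
eh_presence_definite,EH present,MD,12,"12/15 with EH, definite MD"
eh_presence_definite,EH present,VM-MD,2,"2/8 with EH, overlap group"
eh_presence_definite,EH absent,VM,18,complement of 1/19
eh_presence_definite,EH absent,MD,3,complement of 12/15
eh_presence_definite,EH absent,VM-MD,6,complement of 2/8
eh_presence_probable,EH present,VM,1,"1/6 with EH, probable VM"
eh_presence_probable,EH present,MD,10,"10/14 with EH, probable MD"
eh_presence_probable,EH present,VM-MD,2,"2/8 with EH, overlap group"
eh_presence_probable,EH absent,VM,5,complement of 1/6
eh_presence_probable,EH absent,MD,4,complement of 10/14
eh_presence_probable,EH absent,VM-MD,6,complement of 2/8
headache_all,headache,VM,25,25/25 headache symptoms
headache_all,headache,MD,7,7/29 headache symptoms
headache_all,headache,VM-MD,5,5/8 headache symptoms
headache_all,no headache,VM,0,complement of 25/25
headache_all,no headache,MD,22,complement of 7/29
headache_all,no headache,VM-MD,3,complement of 5/8
headache_definite,headache,VM,19,19/19 headache symptoms
headache_definite,headache,MD,4,4/15 headache symptoms
headache_definite,headache,VM-MD,5,5/8 headache symptoms
headache_definite,no headache,VM,0,complement of 19/19
headache_definite,no headache,MD,11,complement of 4/15
headache_definite,no headache,VM-MD,3,complement of 5/8
tinnitus3_all,none,VM,14,25 minus 11 with tinnitus
tinnitus3_all,none,MD,5,29 minus 24 with tinnitus
tinnitus3_all,none,VM-MD,2,8 minus 6 with tinnitus
tinnitus3_all,bilateral,VM,7,7/25 bilateral tinnitus
tinnitus3_all,bilateral,MD,4,4/29 bilateral tinnitus
tinnitus3_all,bilateral,VM-MD,1,1/8 bilateral tinnitus
tinnitus3_all,ipsilateral,VM,4,4/25 ipsilateral tinnitus
tinnitus3_all,ipsilateral,MD,20,20/29 ipsilateral tinnitus
tinnitus3_all,ipsilateral,VM-MD,5,5/8 ipsilateral tinnitus
tinnitus3_definite,none,VM,10,19 minus 9 with tinnitus
tinnitus3_definite,none,MD,1,15 minus 14 with tinnitus
tinnitus3_definite,none,VM-MD,2,8 minus 6 with tinnitus
tinnitus3_definite,bilateral,VM,6,6/19 bilateral tinnitus
tinnitus3_definite,bilateral,MD,2,2/15 bilateral tinnitus
tinnitus3_definite,bilateral,VM-MD,1,1/8 bilateral tinnitus
tinnitus3_definite,ipsilateral,VM,3,3/19 ipsilateral tinnitus
tinnitus3_definite,ipsilateral,MD,12,12/15 ipsilateral tinnitus
tinnitus3_definite,ipsilateral,VM-MD,5,5/8 ipsilateral tinnitus
eh_location_by_deficit,no EH,normal,19,printed row sums to 35
eh_location_by_deficit,no EH,vestibular deficit,8,
eh_location_by_deficit,no EH,cochlear deficit,6,
eh_location_by_deficit,no EH,vestibulocochlear deficit,2,
eh_location_by_deficit,vestibular EH,normal,0,
eh_location_by_deficit,vestibular EH,vestibular deficit,1,
eh_location_by_deficit,vestibular EH,cochlear deficit,0,
eh_location_by_deficit,vestibular EH,vestibulocochlear deficit,0,
eh_location_by_deficit,cochlear EH,normal,4,
eh_location_by_deficit,cochlear EH,vestibular deficit,2,
eh_location_by_deficit,cochlear EH,cochlear deficit,2,
eh_location_by_deficit,cochlear EH,vestibulocochlear deficit,4,
eh_location_by_deficit,vestibular and cochlear EH,normal,1,
eh_location_by_deficit,vestibular and cochlear EH,vestibular deficit,2,
eh_location_by_deficit,vestibular and cochlear EH,cochlear deficit,4,
eh_location_by_deficit,vestibular and cochlear EH,vestibulocochlear deficit,7,
eh_laterality_by_deficit_side,no EH,normal,22,printed row sums to 34
eh_laterality_by_deficit_side,no EH,right-sided deficit,3,
eh_laterality_by_deficit_side,no EH,left-sided deficit,5,
eh_laterality_by_deficit_side,no EH,bilateral deficit,4,
eh_laterality_by_deficit_side,right-sided EH,normal,4,
eh_laterality_by_deficit_side,right-sided EH,right-sided deficit,8,
eh_laterality_by_deficit_side,right-sided EH,left-sided deficit,1,
eh_laterality_by_deficit_side,right-sided EH,bilateral deficit,1,
eh_laterality_by_deficit_side,left-sided EH,normal,0,
eh_laterality_by_deficit_side,left-sided EH,right-sided deficit,0,
eh_laterality_by_deficit_side,left-sided EH,left-sided deficit,9,
eh_laterality_by_deficit_side,left-sided EH,bilateral deficit,1,
eh_laterality_by_deficit_side,bilateral EH,normal,2,
eh_laterality_by_deficit_side,bilateral EH,right-sided deficit,1,
eh_laterality_by_deficit_side,bilateral EH,left-sided deficit,1,
eh_laterality_by_deficit_side,bilateral EH,bilateral deficit,0,
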