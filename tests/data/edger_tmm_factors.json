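{
 "0": [
  0.986713262196224,
  0.777134598928423,
  1.10579970909738,
  0.983136394466452,
  1.22552303678514,
  0.97881601324565
 ],
 "1": [
  0.992013997071882,
  0.965262091575843,
  1.04432806528495
 ],
 "2": [
  0.815692132868456,
  1.04116443539705,
  1.198586263396,
  1.07941803694901,
  0.845513330537357,
  1.07640318820351
 ],
 "3": [
  1.01531492268268,
  1.07327730930274,
  0.917671581941298
 ],
 "4": [
  1.00396045555923,
  1.01073556879162,
  0.998780319978062,
  0.986678960071692
 ],
 "5": [
  0.996074423736478,
  1.02362446911438,
  0.981865685881335,
  0.998884949788616
 ],
 "6": [
  1.01694961236276,
  0.97208594533962,
  1.036487132853,
  0.982851642241478,
  0.992988041039099
 ],
 "7": [
  0.963852325719535,
  0.963837180305095,
  1.01542829964276,
  1.02855525729439,
  1.03064460396058
 ],
 "8": [
  1.02334294690319,
  0.994348591502543,
  0.98274340140003
 ],
 "9": [
  1.01287758186467,
  1.00715206264201,
  0.957328439161297,
  1.0144835717759,
  1.00935052986676
 ],
 "10": [
  0.973635539351658,
  1.04173439259556,
  0.985931130329319
 ],
 "11": [
  1.09920651393027,
  1.01964673852971,
  0.96762487643131,
  0.922070116634691
 ],
 "12": [
  1.02013569772714,
  0.964187995426121,
  0.992966822369978,
  1.03108228818706,
  0.993006909403408
 ],
 "13": [
  0.976051392410251,
  1.01063387543667,
  1.01383056320378,
  0.999926513285826
 ],
 "14": [
  0.97281293578215,
  1.05911470406278,
  0.917628003459927,
  1.05377705445493,
  1.06942586727375,
  0.938559013062732
 ],
 "15": [
  0.959049989152158,
  0.986390397525615,
  1.05708502245893
 ],
 "16": [
  1.00779592919424,
  1.01337275510691,
  0.941320742455844,
  1.06216166745054,
  0.979331950645792
 ],
 "17": [
  0.982794591359249,
  1.01996895098688,
  0.993049466474728,
  0.988712094714661,
  1.03798529565342,
  0.978854992520492
 ],
 "18": [
  1.02856426206277,
  0.984116405177804,
  0.979996609961963,
  0.960194383273142,
  1.04987685933174
 ],
 "19": [
  0.987815541942425,
  1.0044403412992,
  0.99473686033436,
  0.966148871881458,
  1.04869147086928
 ]
}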