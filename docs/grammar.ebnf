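(* Concrete grammar of PBLSTL specification files.
   Whitespace-insensitive; '#' starts a line comment.  A specification is
   one or more probabilistic statements. *)

specification  = statement , { statement } ;

statement      = "P" , prob_comparator , probability , "[" , formula , "]" ;
prob_comparator= "<" | "<=" | ">" | ">=" ;
probability    = number ;                      (* strictly inside (0, 1) *)

(* Boolean and temporal layer; precedence from loosest to tightest:
   <=>  =>  U  V/|  ^/&  unary *)
formula        = implication , { "<=>" , implication } ;
implication    = until_expr , [ "=>" , implication ] ;
until_expr     = disjunction , [ "U" , bounds , disjunction ] ;
disjunction    = conjunction , { ( "V" | "|" ) , conjunction } ;
conjunction    = unary , { ( "^" | "&" ) , unary } ;
unary          = ( "~" | "!" ) , unary
               | "F" , bounds , unary
               | "G" , bounds , unary
               | "X" , "[" , integer , "]" , unary
               | "(" , formula , ")"
               | comparison ;
bounds         = "[" , number , "," , number , "]" ;   (* 0 <= a <= b *)

comparison     = numeric , comparator , numeric ;
comparator     = "<" | "<=" | "=" | ">=" | ">" ;

(* numeric layer *)
numeric        = number
               | "-" , number
               | state_variable
               | "d" , "(" , numeric , ")"
               | unary_fn , "(" , numeric , ")"
               | binary_fn , "(" , numeric , "," , numeric , ")"
               | statistic
               | measure_name ;                (* filter constraints only *)
state_variable = "{" , name , "}" ;            (* not inside filters *)
unary_fn       = "abs" | "ceil" | "floor" | "round" | "sign" | "sqrt" | "trunc" ;
binary_fn      = "add" | "subtract" | "multiply" | "divide" | "power"
               | "min" | "max" ;               (* numeric first argument *)

statistic      = "count" , "(" , collection , ")"
               | simple_stat , "(" , collection , "," , measure_name , ")"
               | "percentile" , "(" , collection , "," , measure_name , "," , number , ")"
               | "covariance" , "(" , collection , "," , measure_name , ","
                              , collection , "," , measure_name , ")" ;
simple_stat    = "mean" | "median" | "mode" | "min" | "max" | "sum" | "stdev" ;

collection     = "regions" | "clusters"
               | "filter" , "(" , collection , "," , constraint , ")" ;

(* constraints reuse the Boolean grammar but range over spatial measures
   only: no temporal operators, state variables or nested collections *)
constraint     = formula ;

measure_name   = "clusteredness" | "density" | "area" | "perimeter"
               | "distanceFromOrigin" | "angle" | "triangularMeasure"
               | "rectangularMeasure" | "circularMeasure"
               | "centroidX" | "centroidY" ;

number         = digit , { digit } , [ "." , { digit } ]
               | "." , digit , { digit } ;
integer        = digit , { digit } ;
name           = letter_or_underscore , { letter_or_digit_or_underscore } ;
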